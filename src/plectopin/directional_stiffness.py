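"""Direction-dependent local bending stiffness from dinucleotide covariances.

Thermal tilt/roll fluctuations of each dinucleotide step are summed over a
loop, with each step's 2x2 covariance co-rotated by the cumulative intrinsic
twist so that all contributions are expressed in the (tilt, roll) axes of
the material frame at the loop center — the same frame in which the
preferred bend direction ``phi_B`` is measured. Under the worm-like-chain
relation, the mean-square bend angle accumulated over contour length
``L = rise * N`` in one bending plane is ``L / A``, so the directional
persistence length is

    A(N, i, phi) = rise * N / (u(phi)^T Sigma_tot u(phi)),

with ``u(phi)`` the unit vector of the bending plane in (tilt, roll)
coordinates. For an isotropic per-step covariance ``s^2 I`` this reduces to
the constant ``rise / s^2``, which the shipped table calibrates to the
50 nm bulk persistence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dinuc_params import DinucParamSet
from .helix_geometry import encode_sequence

__all__ = [
    "StiffnessSummary",
    "summed_covariance",
    "summed_covariance_profile",
    "directional_persistence_length",
    "DEFAULT_A_CEILING",
]

logger = logging.getLogger(__name__)

#: cap on A (nm) when the directional variance underflows (degenerate input)
DEFAULT_A_CEILING = 1e4


@dataclass
class StiffnessSummary:
    """Accumulated stiffness of one loop: center, size and Sigma_tot."""

    center: int
    loop_size: int
    sigma_total: np.ndarray  # 2x2, radians^2
    rise: float

    def persistence_length(self, phi: float, ceiling: float = DEFAULT_A_CEILING) -> float:
        return directional_persistence_length(
            self.sigma_total, self.loop_size, phi, self.rise, ceiling=ceiling
        )


def _rot2(psi: np.ndarray) -> np.ndarray:
    c, s = np.cos(psi), np.sin(psi)
    return np.stack(
        [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
    )


def summed_covariance(
    seq: str | np.ndarray,
    center: int,
    loop_size: int,
    params: DinucParamSet,
    circular: bool = False,
) -> np.ndarray:
    """Sigma_tot for the loop of ``loop_size`` bp centered at ``center``.

    Sums ``R(psi_k) Sigma_step R(psi_k)^T`` over the steps of the loop,
    where ``psi_k`` is the cumulative intrinsic twist from the loop center
    to step ``k`` (negative upstream), so the result lives in the center
    frame's tilt/roll axes.
    """
    idx = seq if isinstance(seq, np.ndarray) else encode_sequence(str(seq))
    n = idx.size
    lo = center - loop_size // 2
    hi = lo + loop_size  # loop_size dinucleotide steps: lo .. hi-1
    if circular:
        take = np.arange(lo, hi) % n
        nxt = np.arange(lo + 1, hi + 1) % n
        steps = 4 * idx[take] + idx[nxt]
    else:
        if lo < 0 or hi > n - 1:
            raise IndexError(
                f"loop [{lo}, {hi}] out of support for a linear {n}-bp sequence"
            )
        steps = 4 * idx[lo:hi] + idx[lo + 1 : hi + 1]
    twists = params.twist_arr[steps]
    # cumulative twist from the loop center to the start of step k
    rel = np.cumsum(twists) - twists  # twist from lo to step k
    psi = rel - rel[center - lo]
    rots = _rot2(psi)
    covs = params.cov_arr[steps]
    return np.einsum("kab,kbc,kdc->ad", rots, covs, rots)


def summed_covariance_profile(
    idx: np.ndarray,
    loop_size: int,
    params: DinucParamSet,
) -> np.ndarray:
    """Vectorized Sigma_tot(i) for every supported center of a linear index
    array; rows with partial support are NaN.

    Uses the invariant decomposition of a symmetric 2x2 matrix under
    rotation: the trace is invariant, while the deviatoric part
    ``(d, c) = ((s_tt - s_rr)/2, s_tr)`` rotates at twice the frame angle,
    so prefix sums of ``(d + i c) * exp(2 i psi)`` give all windowed sums
    in O(n).
    """
    n = idx.size
    steps = 4 * idx[:-1] + idx[1:]
    twists = params.twist_arr[steps]
    covs = params.cov_arr[steps]
    tr = covs[:, 0, 0] + covs[:, 1, 1]
    dev = 0.5 * (covs[:, 0, 0] - covs[:, 1, 1]) + 1j * covs[:, 0, 1]
    # psi0[k]: cumulative twist from sequence start to the start of step k
    psi0 = np.concatenate([[0.0], np.cumsum(twists)[:-1]])
    z = dev * np.exp(2j * psi0)
    cum_tr = np.concatenate([[0.0], np.cumsum(tr)])
    cum_z = np.concatenate([[0.0 + 0.0j], np.cumsum(z)])
    half = loop_size // 2
    out = np.full((n, 2, 2), np.nan)
    centers = np.arange(half, n - half)
    lo, hi = centers - half, centers + half
    trace = cum_tr[hi] - cum_tr[lo]
    zc = (cum_z[hi] - cum_z[lo]) * np.exp(-2j * psi0[centers])
    d, c = zc.real, zc.imag
    out[centers, 0, 0] = 0.5 * trace + d
    out[centers, 1, 1] = 0.5 * trace - d
    out[centers, 0, 1] = c
    out[centers, 1, 0] = c
    return out


def directional_persistence_length(
    sigma: np.ndarray,
    loop_size: int,
    phi: float | np.ndarray,
    rise: float,
    ceiling: float = DEFAULT_A_CEILING,
) -> float | np.ndarray:
    """Persistence length (nm) for bending in plane ``phi`` (radians).

    ``phi`` is measured in (tilt, roll) coordinates; the result is
    pi-periodic (a bending plane, not a signed direction). Degenerate
    (near-zero) directional variance is capped at ``ceiling`` nm.
    """
    sigma = np.asarray(sigma, dtype=float)
    u = np.stack(
        [np.cos(np.asarray(phi, dtype=float)), np.sin(np.asarray(phi, dtype=float))],
        axis=-1,
    )
    var = np.einsum("...a,...ab,...b->...", u, sigma, u)
    length = rise * loop_size
    with np.errstate(divide="ignore"):
        a = np.where(var > length / ceiling, length / var, ceiling)
    if np.any(var <= length / ceiling):
        logger.warning(
            "directional variance underflow: persistence length capped at %g nm",
            ceiling,
        )
    if a.ndim == 0:
        return float(a)
    return a
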