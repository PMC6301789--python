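"""Boltzmann-weighted plectoneme density along a DNA sequence.

For every supported center position ``i`` the model evaluates the total
tip-loop energy ``E_total(N, i, phi) = C N + E_bend(N, i, phi)`` on a grid
of candidate loop sizes (40-120 bp in 8-bp increments) and eight bend
directions anchored at the preferred direction (``phi = phi_B + k * 45
degrees``), converts each conformation to a Boltzmann weight
``W = exp(-E_total)`` and sums the grid:

    W_tot(i) = sum over N, phi of exp(-E_total(N, i, phi)).

``W_tot`` normalized to unit mean over the molecule is the predicted
plectoneme density, directly comparable to experimentally measured
densities (which use the same normalization); ``-ln W_tot`` is the
effective free-energy landscape for placing a plectoneme tip at ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dinuc_params import DinucParamSet, load_param_set
from .directional_stiffness import (
    DEFAULT_A_CEILING,
    summed_covariance_profile,
)
from .helix_geometry import (
    DEFAULT_TANGENT_WINDOW,
    curvature_profile,
    encode_sequence,
    ground_state_path,
)
from .loop_energetics import (
    DEFAULT_BEND_ANGLE_DEG,
    DEFAULT_TENSION_PN,
    work_coefficient,
)

__all__ = [
    "DEFAULT_LOOP_SIZES",
    "DEFAULT_N_DIRECTIONS",
    "DEFAULT_FWHM_BP",
    "EnergyGrid",
    "DensityProfile",
    "energy_grid",
    "density_profile",
    "gaussian_smooth",
    "min_sequence_length",
]

logger = logging.getLogger(__name__)

#: candidate tip-loop sizes (bp): 40 to 120 in 8-bp increments
DEFAULT_LOOP_SIZES: tuple[int, ...] = tuple(range(40, 121, 8))
#: bend directions: every 45 degrees starting from phi_B
DEFAULT_N_DIRECTIONS = 8
#: Gaussian smoothing FWHM (bp) matching the single-molecule assay resolution
DEFAULT_FWHM_BP = 1600


def min_sequence_length(
    loop_sizes: Sequence[int] = DEFAULT_LOOP_SIZES,
    tangent_window: int = DEFAULT_TANGENT_WINDOW,
    circular: bool = False,
) -> int:
    """Shortest sequence with at least one fully supported center."""
    reach = max(loop_sizes) // 2 + (tangent_window - 1) // 2
    return 2 * reach + 1 if not circular else max(loop_sizes) + tangent_window


@dataclass
class EnergyGrid:
    """E_total and Boltzmann weights over (loop size, bend direction) at one
    center position."""

    center: int
    loop_sizes: np.ndarray  # (nN,)
    phis: np.ndarray  # (nN, nphi) absolute bend directions, radians
    theta: np.ndarray  # (nN,) degrees
    phi_b: np.ndarray  # (nN,) radians
    a_nm: np.ndarray  # (nN, nphi) directional persistence lengths
    e_total: np.ndarray  # (nN, nphi) kBT
    weights: np.ndarray  # (nN, nphi) exp(-E_total)

    @property
    def w_tot(self) -> float:
        return float(self.weights.sum())


@dataclass
class DensityProfile:
    """Per-base W_tot, normalized density and free-energy landscape."""

    w_tot: np.ndarray  # NaN outside support
    density: np.ndarray  # W_tot / mean over defined positions
    free_energy: np.ndarray  # -ln W_tot, kBT
    defined_mask: np.ndarray
    circular: bool
    tension_pn: float
    param_set: str
    smoothed_density: np.ndarray | None = None
    smoothing: str | None = None

    def __len__(self) -> int:
        return self.w_tot.size

    def smoothed(self, fwhm: float = DEFAULT_FWHM_BP) -> "DensityProfile":
        """Return a copy with ``smoothed_density`` set (Gaussian, FWHM bp)."""
        sm = gaussian_smooth(
            self.density,
            fwhm=fwhm,
            circular=self.circular,
            defined_mask=self.defined_mask,
        )
        return replace(
            self, smoothed_density=sm, smoothing=f"gaussian fwhm={fwhm} bp"
        )


def _directional_variance(
    sigma: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """u^T Sigma u for the physical bend azimuth phi (measured in the
    center frame's normal/binormal plane).

    A bend along azimuth phi corresponds to the (tilt, roll) direction
    (cos phi, -sin phi): tilt deflects the tangent along +n, roll along -b.
    """
    c, s = np.cos(phi), np.sin(phi)
    return (
        sigma[..., 0, 0] * c * c
        + sigma[..., 1, 1] * s * s
        - 2.0 * sigma[..., 0, 1] * c * s
    )


def density_profile(
    seq: str,
    tension_pn: float = DEFAULT_TENSION_PN,
    params: DinucParamSet | str | None = None,
    circular: bool = False,
    loop_sizes: Sequence[int] = DEFAULT_LOOP_SIZES,
    n_directions: int = DEFAULT_N_DIRECTIONS,
    tangent_window: int = DEFAULT_TANGENT_WINDOW,
    bend_angle_deg: float = DEFAULT_BEND_ANGLE_DEG,
    a_ceiling: float = DEFAULT_A_CEILING,
    ambiguous: str = "strict",
) -> DensityProfile:
    """Predicted plectoneme density for one sequence.

    Linear sequences shorter than :func:`min_sequence_length` are rejected;
    the unsupported leading/trailing stretch of a linear molecule is
    reported as NaN, never as zero.
    """
    if params is None or isinstance(params, str):
        params = load_param_set(params or "default")
    idx = encode_sequence(seq, ambiguous=ambiguous)
    n = idx.size
    loop_sizes = np.asarray(sorted(loop_sizes), dtype=int)
    reach = int(loop_sizes.max()) // 2 + (tangent_window - 1) // 2
    min_len = min_sequence_length(loop_sizes, tangent_window, circular)
    if n < min_len:
        raise ValueError(
            f"sequence of {n} bp too short: the loop-size grid needs at "
            f"least {min_len} bp ({'circular' if circular else 'linear'})"
        )
    path = ground_state_path(
        seq, params, circular=circular, ambiguous=ambiguous, pad=reach + 1
    )
    if circular:
        pad = path.offset
        idx_ext = np.concatenate([idx[-pad:], idx, idx[:pad]])
        sl = slice(pad, pad + n)
    else:
        idx_ext = idx
        sl = slice(None)

    c_work = work_coefficient(tension_pn, params.rise)
    prefactor = (bend_angle_deg / 360.0) ** 2 * 2.0 * np.pi**2
    k_phi = np.arange(n_directions) * (2.0 * np.pi / n_directions)
    cos_k = np.cos(k_phi)

    w_tot = np.zeros(n)
    for n_loop in loop_sizes:
        curv = curvature_profile(path, int(n_loop), tangent_window)
        theta = curv.theta  # degrees, len n
        phi_b = curv.phi_b
        sigma = summed_covariance_profile(idx_ext, int(n_loop), params)[sl]
        mask = ~np.isnan(theta) & ~np.isnan(sigma[:, 0, 0])
        phis = phi_b[mask, None] + k_phi[None, :]
        var = _directional_variance(sigma[mask][:, None, :, :], phis)
        length = params.rise * float(n_loop)
        # E_bend = prefactor * A / (rise * N) * deficit = prefactor * deficit / var
        var_eff = np.maximum(var, length / a_ceiling)
        x = (theta[mask] / bend_angle_deg)[:, None]
        deficit = 1.0 + x * x - 2.0 * x * cos_k[None, :]
        e_total = c_work * float(n_loop) + prefactor * deficit / var_eff
        w_tot[mask] += np.exp(-e_total).sum(axis=1)

    # support is set by the largest loop size
    defined = np.zeros(n, dtype=bool)
    if circular:
        defined[:] = True
    else:
        defined[reach : n - reach] = True
    w = np.full(n, np.nan)
    w[defined] = w_tot[defined]
    density = np.full(n, np.nan)
    density[defined] = w[defined] / w[defined].mean()
    free_energy = np.full(n, np.nan)
    free_energy[defined] = -np.log(w[defined])
    return DensityProfile(
        w_tot=w,
        density=density,
        free_energy=free_energy,
        defined_mask=defined,
        circular=circular,
        tension_pn=tension_pn,
        param_set=params.name,
    )


def energy_grid(
    seq: str,
    center: int,
    tension_pn: float = DEFAULT_TENSION_PN,
    params: DinucParamSet | str | None = None,
    circular: bool = False,
    loop_sizes: Sequence[int] = DEFAULT_LOOP_SIZES,
    n_directions: int = DEFAULT_N_DIRECTIONS,
    tangent_window: int = DEFAULT_TANGENT_WINDOW,
    bend_angle_deg: float = DEFAULT_BEND_ANGLE_DEG,
    a_ceiling: float = DEFAULT_A_CEILING,
) -> EnergyGrid:
    """Full (loop size x direction) energy and weight grid at one center."""
    from .directional_stiffness import (
        directional_persistence_length,
        summed_covariance,
    )

    if params is None or isinstance(params, str):
        params = load_param_set(params or "default")
    loop_arr = np.asarray(sorted(loop_sizes), dtype=int)
    reach = int(loop_arr.max()) // 2 + (tangent_window - 1) // 2
    idx = encode_sequence(seq)
    n = idx.size
    if not circular and not reach <= center <= n - 1 - reach:
        raise IndexError(
            f"center {center} unsupported on a linear {n}-bp sequence "
            f"(needs {reach} bp of context on each side)"
        )
    path = ground_state_path(seq, params, circular=circular, pad=reach + 1)
    c_work = work_coefficient(tension_pn, params.rise)
    k_phi = np.arange(n_directions) * (2.0 * np.pi / n_directions)
    nn, nphi = loop_arr.size, n_directions
    theta = np.empty(nn)
    phi_b = np.empty(nn)
    a_nm = np.empty((nn, nphi))
    e_tot = np.empty((nn, nphi))
    phis = np.empty((nn, nphi))
    for j, n_loop in enumerate(loop_arr):
        curv = curvature_profile(path, int(n_loop), tangent_window)
        theta[j] = curv.theta[center]
        phi_b[j] = curv.phi_b[center]
        sigma = summed_covariance(idx, center, int(n_loop), params, circular)
        for k in range(nphi):
            phi = phi_b[j] + k_phi[k]
            phis[j, k] = phi
            # physical azimuth -> (tilt, roll) plane direction
            a_nm[j, k] = directional_persistence_length(
                sigma, int(n_loop), -phi, params.rise, ceiling=a_ceiling
            )
            x = theta[j] / bend_angle_deg
            deficit = 1.0 + x * x - 2.0 * x * np.cos(phi - phi_b[j])
            e_bend = (
                (bend_angle_deg / 360.0) ** 2
                * 2.0
                * np.pi**2
                * a_nm[j, k]
                / (params.rise * float(n_loop))
                * deficit
            )
            e_tot[j, k] = c_work * float(n_loop) + e_bend
    return EnergyGrid(
        center=center,
        loop_sizes=loop_arr,
        phis=phis,
        theta=theta,
        phi_b=phi_b,
        a_nm=a_nm,
        e_total=e_tot,
        weights=np.exp(-e_tot),
    )


def gaussian_smooth(
    values: np.ndarray,
    fwhm: float = DEFAULT_FWHM_BP,
    circular: bool = False,
    defined_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian smoothing with sigma = fwhm / sqrt(8 ln 2).

    Circular profiles wrap; linear profiles use a truncated, per-position
    renormalized kernel over the defined positions, then an exact rescale
    so the mean over defined positions is preserved.
    """
    if fwhm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm}")
    values = np.asarray(values, dtype=float)
    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    if defined_mask is None:
        defined_mask = ~np.isnan(values)
    out = np.full(values.shape, np.nan)
    v = values[defined_mask]
    if v.size == 0:
        return out
    if circular and defined_mask.all():
        out[:] = gaussian_filter1d(values, sigma, mode="wrap")
        return out
    num = gaussian_filter1d(v, sigma, mode="constant", cval=0.0)
    den = gaussian_filter1d(np.ones_like(v), sigma, mode="constant", cval=0.0)
    sm = num / den
    mean_in = v.mean()
    mean_sm = sm.mean()
    if mean_sm != 0:
        sm *= mean_in / mean_sm
    out[defined_mask] = sm
    return out
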