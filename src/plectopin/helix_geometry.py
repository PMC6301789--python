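"""Intrinsic (ground-state) 3D path of a DNA sequence and its curvature.

The ground state is built by composing, per dinucleotide step, the step's
intrinsic twist, roll and tilt rotations of a local orthonormal material
frame (tangent ``t``, normal ``n``, binormal ``b``) and advancing one
base-pair rise along the new tangent. Rotation convention (fixed and
documented, see the methods note): intrinsic composition twist about ``t``,
then roll about the rolled frame's ``n``, then tilt about ``b``.

Local tangents are chords of the path over an 11-bp window (one helical
turn, ~3.7 nm), which cancels the intra-turn wobble of the helical path.
The intrinsic curvature ``theta(N, i)`` of an N-bp stretch centered at
``i`` is the angle between the windowed tangents at the two ends, and the
preferred bend direction ``phi_B(N, i)`` is the azimuth, in the material
frame at ``i``, of the end-tangent change perpendicular to the tangent
at ``i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dinuc_params import DinucParamSet

__all__ = [
    "HelixPath",
    "CurvatureProfile",
    "SequenceError",
    "encode_sequence",
    "ground_state_path",
    "windowed_tangent",
    "windowed_tangents",
    "curvature_profile",
    "DEFAULT_TANGENT_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_TANGENT_WINDOW = 11

_BASE_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

# IUPAC ambiguity codes -> fixed representative base (policy="substitute")
_IUPAC_REPR = {
    "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A", "U": "T",
}


class SequenceError(ValueError):
    """Raised for sequences outside the ACGT alphabet (strict policy)."""


def encode_sequence(seq: str, ambiguous: str = "strict") -> np.ndarray:
    """Map a DNA string to base indices 0..3 (A, C, G, T).

    ``ambiguous="strict"`` rejects any non-ACGT character, reporting its
    offset; ``ambiguous="substitute"`` maps IUPAC codes to a fixed
    representative base with a logged warning.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = _BASE_INDEX[arr]
    bad = np.nonzero(idx < 0)[0]
    if bad.size:
        if ambiguous == "substitute":
            chars = {seq[j].upper() for j in bad}
            unknown = chars - set(_IUPAC_REPR)
            if unknown:
                raise SequenceError(
                    f"non-IUPAC character(s) {sorted(unknown)} at offset {bad[0]}"
                )
            logger.warning(
                "substituting %d ambiguous base(s) (%s) with fixed representatives",
                bad.size,
                ",".join(sorted(chars)),
            )
            subs = seq.upper()
            for c, rep in _IUPAC_REPR.items():
                subs = subs.replace(c, rep)
            return encode_sequence(subs, ambiguous="strict")
        raise SequenceError(
            f"non-ACGT base {seq[bad[0]]!r} at offset {int(bad[0])} "
            "(use ambiguous='substitute' to map IUPAC codes)"
        )
    return idx.astype(np.intp)


@dataclass
class HelixPath:
    """Ground-state 3D trace of a sequence.

    ``positions[k]`` (nm) and ``frames[k]`` (columns t, n, b) refer to base
    pair ``k + offset`` of the input sequence; for circular sequences the
    path is built on a padded copy so that every original base has full
    window support, and ``offset`` maps sequence coordinates to path
    indices.
    """

    positions: np.ndarray  # (M, 3) nm
    frames: np.ndarray  # (M, 3, 3), columns t, n, b
    sequence_length: int  # bp of the original sequence
    circular: bool
    rise: float
    offset: int = 0  # path index of sequence position 0

    def __len__(self) -> int:
        return self.sequence_length


def _step_rotations(
    tilt: np.ndarray, roll: np.ndarray, twist: np.ndarray
) -> np.ndarray:
    """Local-frame rotation matrix per step: Rx(twist) @ Ry(roll) @ Rz(tilt).

    Axes are frame-local: x = t (twist axis), y = n (roll axis),
    z = b (tilt axis); intrinsic composition in the order twist, roll, tilt.
    """
    ct, st = np.cos(twist), np.sin(twist)
    cr, sr = np.cos(roll), np.sin(roll)
    cl, sl = np.cos(tilt), np.sin(tilt)
    n = tilt.shape[0]
    rx = np.zeros((n, 3, 3))
    rx[:, 0, 0] = 1.0
    rx[:, 1, 1] = ct
    rx[:, 1, 2] = -st
    rx[:, 2, 1] = st
    rx[:, 2, 2] = ct
    ry = np.zeros((n, 3, 3))
    ry[:, 1, 1] = 1.0
    ry[:, 0, 0] = cr
    ry[:, 0, 2] = sr
    ry[:, 2, 0] = -sr
    ry[:, 2, 2] = cr
    rz = np.zeros((n, 3, 3))
    rz[:, 2, 2] = 1.0
    rz[:, 0, 0] = cl
    rz[:, 0, 1] = -sl
    rz[:, 1, 0] = sl
    rz[:, 1, 1] = cl
    return rx @ ry @ rz


def ground_state_path(
    seq: str,
    params: DinucParamSet,
    circular: bool = False,
    ambiguous: str = "strict",
    pad: int = 131,
) -> HelixPath:
    """Trace the intrinsic zero-temperature path of ``seq``.

    For circular sequences, ``pad`` bases are wrapped onto each end before
    tracing so that windows crossing the origin see the correct local
    geometry (the returned coordinates still index the original sequence).
    """
    idx = encode_sequence(seq, ambiguous=ambiguous)
    n = idx.size
    if n < 2:
        raise SequenceError("need at least 2 bases to trace a path")
    if circular:
        pad = min(pad, n)
        idx = np.concatenate([idx[-pad:], idx, idx[:pad]])
        offset = pad
    else:
        offset = 0
    steps = 4 * idx[:-1] + idx[1:]
    rot = _step_rotations(
        params.tilt_arr[steps], params.roll_arr[steps], params.twist_arr[steps]
    )
    m = idx.size
    frames = np.empty((m, 3, 3))
    frames[0] = np.eye(3)
    for k in range(m - 1):
        frames[k + 1] = frames[k] @ rot[k]
    positions = np.empty((m, 3))
    positions[0] = 0.0
    np.cumsum(frames[1:, :, 0] * params.rise, axis=0, out=positions[1:])
    return HelixPath(
        positions=positions,
        frames=frames,
        sequence_length=n,
        circular=circular,
        rise=params.rise,
        offset=offset,
    )


def windowed_tangents(
    path: HelixPath, window: int = DEFAULT_TANGENT_WINDOW
) -> np.ndarray:
    """Unit chord tangents for every supported center (NaN where undefined).

    Returned array is indexed by sequence position; ``t[i]`` is the unit
    chord from position ``i - h`` to ``i + h`` with ``h = (window-1)/2``.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("tangent window must be odd and >= 3")
    h = (window - 1) // 2
    n = path.sequence_length
    out = _path_tangents(path, window)[path.offset : path.offset + n]
    return out


def _path_tangents(path: HelixPath, window: int) -> np.ndarray:
    """Chord tangents over raw path indices (padded trace for circular)."""
    h = (window - 1) // 2
    m = path.positions.shape[0]
    out = np.full((m, 3), np.nan)
    chord = path.positions[2 * h :] - path.positions[: m - 2 * h]
    out[h : m - h] = chord / np.linalg.norm(chord, axis=-1, keepdims=True)
    return out


def windowed_tangent(
    path: HelixPath, i: int, window: int = DEFAULT_TANGENT_WINDOW
) -> np.ndarray:
    """Unit chord tangent at a single center position ``i``."""
    if window % 2 != 1 or window < 3:
        raise ValueError("tangent window must be odd and >= 3")
    h = (window - 1) // 2
    n = path.sequence_length
    m = path.positions.shape[0]
    j = i + path.offset
    if j - h < 0 or j + h > m - 1:
        raise IndexError(
            f"tangent window [{i - h}, {i + h}] out of support for a "
            f"{'circular' if path.circular else 'linear'} {n}-bp path"
        )
    chord = path.positions[j + h] - path.positions[j - h]
    return chord / np.linalg.norm(chord)


@dataclass
class CurvatureProfile:
    """theta(N, i) in degrees and phi_B(N, i) in radians per center i."""

    loop_size: int
    theta: np.ndarray  # degrees, NaN outside support
    phi_b: np.ndarray  # radians, 0 where theta == 0
    tangent_window: int = DEFAULT_TANGENT_WINDOW

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.theta)


def curvature_profile(
    path: HelixPath, loop_size: int, tangent_window: int = DEFAULT_TANGENT_WINDOW
) -> CurvatureProfile:
    """Intrinsic curvature and preferred bend direction for every center.

    ``theta`` is the angle between the windowed tangents at
    ``i - loop_size//2`` and ``i + loop_size//2``; ``phi_B`` the azimuth
    (atan2 of the b- and n-components) of the end-tangent change projected
    perpendicular to the center tangent, measured in the material frame at
    the center.
    """
    if loop_size < tangent_window:
        raise ValueError(
            f"loop size {loop_size} smaller than tangent window {tangent_window}"
        )
    n = path.sequence_length
    half = loop_size // 2
    reach = half + (tangent_window - 1) // 2
    if not path.circular and loop_size + tangent_window - 1 > n:
        raise ValueError(
            f"loop size {loop_size} (+ tangent window) exceeds linear "
            f"sequence length {n}"
        )
    if path.circular and path.offset < reach:
        raise ValueError(
            f"circular path padding {path.offset} too small for loop size "
            f"{loop_size}; rebuild the path with pad >= {reach}"
        )
    tang = _path_tangents(path, tangent_window)
    theta = np.full(n, np.nan)
    phi_b = np.full(n, np.nan)
    centers = np.arange(n)
    if path.circular:
        sel = centers
    else:
        sel = centers[(centers - reach >= 0) & (centers + reach <= n - 1)]
    t0 = tang[sel + path.offset - half]
    t1 = tang[sel + path.offset + half]
    dot = np.clip(np.einsum("ij,ij->i", t0, t1), -1.0, 1.0)
    theta[sel] = np.degrees(np.arccos(dot))
    frames = path.frames[sel + path.offset]
    delta = t1 - t0
    # component of the tangent change perpendicular to the center tangent,
    # expressed in the center frame's (n, b) plane
    dn = np.einsum("ij,ij->i", delta, frames[:, :, 1])
    db = np.einsum("ij,ij->i", delta, frames[:, :, 2])
    phi = np.arctan2(db, dn)
    phi[np.hypot(dn, db) < 1e-12] = 0.0  # straight stretch: direction undefined
    phi_b[sel] = phi
    return CurvatureProfile(
        loop_size=loop_size, theta=theta, phi_b=phi_b, tangent_window=tangent_window
    )
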