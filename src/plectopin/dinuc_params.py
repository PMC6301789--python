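"""Dinucleotide geometry and stiffness parameter sets.

A :class:`DinucParamSet` bundles, for each of the 16 dinucleotide steps,

* the intrinsic step geometry — tilt, roll and twist angles (degrees in
  files and reports, radians internally), and
* the thermal step stiffness — a symmetric 2x2 covariance matrix of the
  (tilt, roll) fluctuations in radians^2,

together with the base-pair rise (nm) and the bulk persistence length (nm)
used by the loop-energetics constants.

Parameter values are data, not code: they ship as flat key-value text files
under ``plectopin/data`` with citation headers, and users may point
:func:`load_param_set` at their own files in the same format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "DINUCLEOTIDES",
    "DinucParamSet",
    "ParamFileError",
    "ParamValidationError",
    "load_param_set",
    "validate_param_set",
    "write_param_set",
    "null_param_set",
    "available_sets",
]

#: the 16 dinucleotide steps in lexicographic order
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

#: shipped parameter sets, by name
_SHIPPED = {
    "default": "crystal.tsv",
    "crystal": "crystal.tsv",
    "wedge-alt": "wedge_alt.tsv",
    "null": "null.tsv",
}


class ParamFileError(ValueError):
    """Raised when a parameter file is malformed or incomplete."""


class ParamValidationError(ValueError):
    """Raised when a parameter set violates a physical sanity invariant."""


@dataclass
class DinucParamSet:
    """Validated dinucleotide geometry + stiffness table.

    ``geometry[step]`` is ``(tilt, roll, twist)`` in **radians**;
    ``stiffness[step]`` is the symmetric 2x2 covariance of (tilt, roll)
    fluctuations in radians^2. ``rise`` is the base-pair rise in nm and
    ``bulk_persistence_length`` the bulk bending persistence length in nm.
    """

    name: str
    geometry: dict[str, tuple[float, float, float]]
    stiffness: dict[str, np.ndarray]
    rise: float = 0.334
    bulk_persistence_length: float = 50.0
    provenance: str = ""

    def __post_init__(self) -> None:
        report = validate_param_set(self)
        if report:
            raise ParamValidationError(
                f"parameter set {self.name!r} invalid: " + "; ".join(report)
            )

    # -- array views keyed by step index (4*base1 + base2); rebuilt on
    # access so in-place edits to the dicts are always reflected ----------
    def _geom_column(self, col: int) -> np.ndarray:
        return np.array([self.geometry[s][col] for s in DINUCLEOTIDES])

    @property
    def tilt_arr(self) -> np.ndarray:
        return self._geom_column(0)

    @property
    def roll_arr(self) -> np.ndarray:
        return self._geom_column(1)

    @property
    def twist_arr(self) -> np.ndarray:
        return self._geom_column(2)

    @property
    def cov_arr(self) -> np.ndarray:
        return np.array([self.stiffness[s] for s in DINUCLEOTIDES])

    @property
    def mean_twist(self) -> float:
        """Sequence-averaged helical twist (radians per step)."""
        return float(self.twist_arr.mean())


def _psd(matrix: np.ndarray, tol: float = 1e-12) -> bool:
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        return False
    eig = np.linalg.eigvalsh(matrix)
    return bool(eig.min() >= -tol)


def validate_param_set(pset: DinucParamSet) -> list[str]:
    """Return a list of violated invariants (empty iff the set is valid)."""
    report: list[str] = []
    steps = set(pset.geometry)
    missing = set(DINUCLEOTIDES) - steps
    extra = steps - set(DINUCLEOTIDES)
    if missing:
        report.append(f"missing geometry for step(s): {', '.join(sorted(missing))}")
    if extra:
        report.append(f"unknown step key(s): {', '.join(sorted(extra))}")
    if set(pset.stiffness) != set(DINUCLEOTIDES):
        miss = set(DINUCLEOTIDES) - set(pset.stiffness)
        if miss:
            report.append(f"missing stiffness for step(s): {', '.join(sorted(miss))}")
    for step in sorted(steps & set(DINUCLEOTIDES)):
        twist_deg = math.degrees(pset.geometry[step][2])
        if not 20.0 < twist_deg < 45.0:
            report.append(
                f"twist for step {step} = {twist_deg:.2f} deg outside sane "
                "range (20, 45) deg"
            )
    for step, cov in sorted(pset.stiffness.items()):
        mat = np.asarray(cov, dtype=float)
        if mat.shape != (2, 2):
            report.append(f"stiffness for step {step} is not 2x2")
        elif not _psd(mat):
            report.append(f"stiffness for step {step} not symmetric PSD")
    if not pset.rise > 0:
        report.append(f"rise must be positive, got {pset.rise}")
    if not pset.bulk_persistence_length > 0:
        report.append(
            f"bulk persistence length must be positive, got "
            f"{pset.bulk_persistence_length}"
        )
    return report


def _parse_param_text(text: str, name: str) -> DinucParamSet:
    geometry: dict[str, tuple[float, float, float]] = {}
    stiffness: dict[str, np.ndarray] = {}
    meta = {"rise_nm": 0.334, "bulk_persistence_length_nm": 50.0}
    provenance_lines: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            provenance_lines.append(line.lstrip("# "))
            continue
        if not line:
            continue
        fields = line.split()
        key = fields[0]
        if key in ("name",):
            name = fields[1]
            continue
        if key in meta:
            meta[key] = float(fields[1])
            continue
        if len(key) == 2 and set(key) <= set("ACGT"):
            if len(fields) != 7:
                raise ParamFileError(
                    f"line {lineno}: step record needs 7 fields "
                    "(step tilt roll twist var_tilt var_roll cov_tilt_roll), "
                    f"got {len(fields)}"
                )
            tilt, roll, twist, vt, vr, ctr = (float(x) for x in fields[1:])
            geometry[key] = (
                math.radians(tilt),
                math.radians(roll),
                math.radians(twist),
            )
            stiffness[key] = np.array([[vt, ctr], [ctr, vr]], dtype=float)
            continue
        raise ParamFileError(f"line {lineno}: unrecognized record {key!r}")
    missing = set(DINUCLEOTIDES) - set(geometry)
    if missing:
        raise ParamFileError(
            f"parameter file {name!r} is missing step(s): "
            + ", ".join(sorted(missing))
        )
    return DinucParamSet(
        name=name,
        geometry=geometry,
        stiffness=stiffness,
        rise=meta["rise_nm"],
        bulk_persistence_length=meta["bulk_persistence_length_nm"],
        provenance="\n".join(provenance_lines),
    )


def load_param_set(source: str | Path = "default") -> DinucParamSet:
    """Load a shipped parameter set by name, or a user file by path.

    Shipped names: ``default`` (crystallography-derived step geometry, the
    recommended set), ``wedge-alt`` (an alternative wedge-style set for
    sensitivity checks) and ``null`` (zero curvature, uniform twist; the
    analytic control).
    """
    src = str(source)
    if src in _SHIPPED:
        text = (
            resources.files("plectopin.data").joinpath(_SHIPPED[src]).read_text()
        )
        return _parse_param_text(text, name=src)
    path = Path(source)
    if not path.is_file():
        raise ParamFileError(
            f"unknown parameter set {src!r}: not a shipped name "
            f"({', '.join(sorted(set(_SHIPPED)))}) and not a readable file"
        )
    return _parse_param_text(path.read_text(), name=path.stem)


def _degrees_exact(rad: float) -> float:
    """Degree value whose radian conversion reproduces ``rad`` bit-exactly.

    ``degrees(radians(x))`` can be off by an ulp; nudge the printed degree
    value until the round trip is exact so file round-trips are lossless.
    """
    deg = math.degrees(rad)
    if math.radians(deg) == rad:
        return deg
    for direction in (math.inf, -math.inf):
        cand = deg
        for _ in range(4):
            cand = math.nextafter(cand, direction)
            if math.radians(cand) == rad:
                return cand
    return deg  # give up: sub-ulp mismatch


def write_param_set(pset: DinucParamSet, path: str | Path) -> None:
    """Write a set back to the flat key-value file format (degrees)."""
    lines = [f"# parameter set: {pset.name}"]
    lines += [f"# {ln}" for ln in pset.provenance.splitlines()]
    lines.append(f"name {pset.name}")
    lines.append(f"rise_nm {pset.rise!r}")
    lines.append(f"bulk_persistence_length_nm {pset.bulk_persistence_length!r}")
    lines.append("# step tilt roll twist var_tilt var_roll cov_tilt_roll")
    for step in DINUCLEOTIDES:
        tilt, roll, twist = (_degrees_exact(v) for v in pset.geometry[step])
        cov = pset.stiffness[step]
        lines.append(
            f"{step} {float(tilt)!r} {float(roll)!r} {float(twist)!r} "
            f"{float(cov[0, 0])!r} {float(cov[1, 1])!r} {float(cov[0, 1])!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def null_param_set(
    twist_deg: float = 34.3, per_plane_var: float | None = None
) -> DinucParamSet:
    """Zero-curvature control set: tilt = roll = 0, uniform twist.

    With isotropic per-step stiffness calibrated to the bulk persistence
    length; the test suite uses this as the analytic reference throughout.
    """
    rise, bulk_a = 0.334, 50.0
    var = rise / bulk_a if per_plane_var is None else per_plane_var
    geometry = {s: (0.0, 0.0, math.radians(twist_deg)) for s in DINUCLEOTIDES}
    stiffness = {s: np.eye(2) * var for s in DINUCLEOTIDES}
    return DinucParamSet(
        name="null",
        geometry=geometry,
        stiffness=stiffness,
        rise=rise,
        bulk_persistence_length=bulk_a,
        provenance="analytic control: straight ground state, isotropic stiffness",
    )


def available_sets() -> list[str]:
    return sorted(set(_SHIPPED))
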