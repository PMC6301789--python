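"""Genome-scale scanning and TSS-aligned aggregation of density tracks.

``scan_genome`` evaluates the plectoneme density model over every record of
a FASTA file (optionally circular, e.g. bacterial chromosomes), chunking
long records with enough overlap that the result is independent of the
chunk size. ``tss_metaprofile`` aggregates a track around transcription
start sites, strand-aware (minus-strand windows are reversed so negative
offsets are always upstream of the gene), and smooths the mean profile
with a centered moving average (51 bp by default).

Tracks are exported as bedGraph (1-based input coordinates mapped to the
format's 0-based half-open intervals) or plain TSV; masked positions are
skipped, never zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .dinuc_params import DinucParamSet, load_param_set
from .helix_geometry import DEFAULT_TANGENT_WINDOW
from .plectoneme_density import (
    DEFAULT_LOOP_SIZES,
    DEFAULT_TENSION_PN,
    DensityProfile,
    density_profile,
)

__all__ = [
    "TssTable",
    "MetaProfile",
    "scan_genome",
    "scan_sequence_chunked",
    "tss_metaprofile",
    "read_tss_table",
    "write_bedgraph",
    "read_bedgraph",
    "write_track_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_BP = 200_000


@dataclass
class TssTable:
    """Transcription start sites: chromosome, 1-based position, strand."""

    records: pd.DataFrame  # columns: chrom, position, strand, name

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MetaProfile:
    """Mean track value vs. signed offset from the TSS (negative=upstream)."""

    offsets: np.ndarray
    mean_density: np.ndarray
    n_sites: int
    smoothing_window: int


def scan_sequence_chunked(
    seq: str,
    tension_pn: float = DEFAULT_TENSION_PN,
    params: DinucParamSet | None = None,
    circular: bool = False,
    chunk_bp: int = DEFAULT_CHUNK_BP,
    **kwargs,
) -> DensityProfile:
    """Density profile of one (possibly long) sequence.

    Linear sequences longer than ``chunk_bp`` are evaluated in chunks with
    a one-support-radius overlap; because every model quantity is local to
    a 131-bp window, the chunked result is identical to the monolithic one.
    Circular sequences are never chunked across the origin join.
    """
    if params is None:
        params = load_param_set("default")
    n = len(seq)
    if circular or n <= chunk_bp:
        return density_profile(
            seq, tension_pn, params, circular=circular, **kwargs
        )
    loop_sizes = kwargs.get("loop_sizes", DEFAULT_LOOP_SIZES)
    tangent_window = kwargs.get("tangent_window", DEFAULT_TANGENT_WINDOW)
    reach = max(loop_sizes) // 2 + (tangent_window - 1) // 2
    w = np.full(n, np.nan)
    start = 0
    while start < n:
        stop = min(n, start + chunk_bp)
        lo = max(0, start - reach)
        hi = min(n, stop + reach)
        part = density_profile(
            seq[lo:hi], tension_pn, params, circular=False, **kwargs
        )
        take = slice(start - lo, stop - lo)
        w[start:stop] = part.w_tot[take]
        start = stop
    defined = ~np.isnan(w)
    density = np.full(n, np.nan)
    density[defined] = w[defined] / w[defined].mean()
    free_energy = np.full(n, np.nan)
    free_energy[defined] = -np.log(w[defined])
    return DensityProfile(
        w_tot=w,
        density=density,
        free_energy=free_energy,
        defined_mask=defined,
        circular=False,
        tension_pn=tension_pn,
        param_set=params.name,
    )


def scan_genome(
    fasta: str | Path,
    tension_pn: float = DEFAULT_TENSION_PN,
    params: DinucParamSet | str | None = None,
    circular: bool | Mapping[str, bool] = False,
    chunk_bp: int = DEFAULT_CHUNK_BP,
    **kwargs,
) -> dict[str, DensityProfile]:
    """Per-record density tracks for a (multi-record) genome FASTA.

    ``circular`` may be a single flag or a per-record mapping.
    """
    if params is None or isinstance(params, str):
        params = load_param_set(params or "default")
    tracks: dict[str, DensityProfile] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        circ = (
            circular.get(rec.id, False)
            if isinstance(circular, Mapping)
            else bool(circular)
        )
        logger.info(
            "scanning %s (%d bp, %s)",
            rec.id,
            len(rec.seq),
            "circular" if circ else "linear",
        )
        tracks[rec.id] = scan_sequence_chunked(
            str(rec.seq),
            tension_pn,
            params,
            circular=circ,
            chunk_bp=chunk_bp,
            **kwargs,
        )
    if not tracks:
        raise ValueError(f"no FASTA records found in {fasta}")
    return tracks


def read_tss_table(path: str | Path) -> TssTable:
    """Read a TSS table: 4-column TSV (chrom, position, strand, [name]) or
    BED6 (strand from column 6; positions converted to the 1-based start).
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if len(fields) >= 6 and fields[5] in "+-":
                    # BED6: 0-based half-open; TSS = strand-aware interval start
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5]
                    pos = start + 1 if strand == "+" else end
                    name = fields[3]
                elif 3 <= len(fields) <= 4:
                    chrom, pos, strand = fields[0], int(fields[1]), fields[2]
                    name = fields[3] if len(fields) == 4 else ""
                    if strand not in "+-":
                        raise ValueError(f"bad strand {strand!r}")
                else:
                    raise ValueError(f"unrecognized column count {len(fields)}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            rows.append((chrom, pos, strand, name))
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand", "name"])
    if df.empty:
        raise ValueError(f"TSS table {path} contains no records")
    return TssTable(records=df)


def tss_metaprofile(
    tracks: Mapping[str, DensityProfile] | Mapping[str, np.ndarray],
    tss: TssTable,
    halfwidth: int = 400,
    smooth_window: int = 51,
    use: str = "density",
) -> MetaProfile:
    """Strand-aware mean track profile around TSS.

    Sites whose full window is not defined on the track are dropped (with a
    logged count). ``use`` selects the track component ("density" or
    "free_energy") when ``tracks`` holds :class:`DensityProfile` objects.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS table")
    if smooth_window < 1 or smooth_window % 2 != 1:
        raise ValueError("smoothing window must be an odd positive integer")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    acc = np.zeros(offsets.size)
    n_used = 0
    n_dropped = 0
    for row in tss.records.itertuples(index=False):
        track = tracks.get(row.chrom)
        if track is None:
            n_dropped += 1
            continue
        values = track.density if isinstance(track, DensityProfile) else track
        if use == "free_energy" and isinstance(track, DensityProfile):
            values = track.free_energy
        center = row.position - 1  # 1-based -> 0-based
        lo, hi = center - halfwidth, center + halfwidth + 1
        if lo < 0 or hi > values.size:
            n_dropped += 1
            continue
        window = values[lo:hi]
        if np.isnan(window).any():
            n_dropped += 1
            continue
        if row.strand == "-":
            window = window[::-1]
        acc += window
        n_used += 1
    if n_dropped:
        logger.warning("dropped %d TSS site(s) without full track support",
                       n_dropped)
    if n_used == 0:
        raise ValueError("no TSS site has full track support")
    mean = acc / n_used
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(mean, pad, mode="edge")
        mean = np.convolve(padded, kernel, mode="valid")
    return MetaProfile(
        offsets=offsets,
        mean_density=mean,
        n_sites=n_used,
        smoothing_window=smooth_window,
    )


def write_bedgraph(
    track: DensityProfile | np.ndarray,
    path: str | Path,
    chrom: str = "chr",
    which: str = "density",
) -> None:
    """Write a per-base track as bedGraph (0-based half-open records).

    Consecutive equal values are merged into one interval; masked (NaN)
    positions produce no records.
    """
    values = (
        getattr(track, which) if isinstance(track, DensityProfile) else track
    )
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        start = None
        current = None
        for i, v in enumerate(values):
            if np.isnan(v):
                if start is not None:
                    fh.write(f"{chrom}\t{start}\t{i}\t{current:.6g}\n")
                    start = None
                continue
            if start is None:
                start, current = i, v
            elif v != current:
                fh.write(f"{chrom}\t{start}\t{i}\t{current:.6g}\n")
                start, current = i, v
        if start is not None:
            fh.write(f"{chrom}\t{start}\t{values.size}\t{current:.6g}\n")


def read_bedgraph(path: str | Path, length: int | None = None) -> dict[str, np.ndarray]:
    """Read a bedGraph file back into per-base arrays (NaN where absent)."""
    frames: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}, line {lineno}: need 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            frames.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, ivs in frames.items():
        size = length or max(end for _, end, _ in ivs)
        arr = np.full(size, np.nan)
        for start, end, value in ivs:
            arr[start:end] = value
        out[chrom] = arr
    return out


def write_track_tsv(
    track: DensityProfile, path: str | Path, chrom: str = "chr"
) -> None:
    """Plain TSV export: 1-based position, density, free energy (kBT)."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "position": np.arange(1, len(track) + 1),
            "density": track.density,
            "free_energy_kBT": track.free_energy,
        }
    )
    df = df[track.defined_mask]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
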