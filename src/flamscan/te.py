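"""Transposable-element annotations and strand-resolved bin coverage.

Ingests TE annotations (BED6 or GFF3, EDTA/RepeatMasker-style), selects
Gypsy-family elements, computes the fraction of every bin covered by
selected features on each strand, and discretises the two fractions into
the model's 3-symbol emission alphabet:

* ``0`` — no strand reaches the coverage threshold,
* ``1`` — exactly one strand reaches it,
* ``2`` — both strands reach it.

Overlapping same-strand features are unioned (a base covered twice counts
once), so fractions never exceed 1. Coverage of the truncated trailing bin
of a contig is normalised by its true width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import BinGrid

logger = logging.getLogger(__name__)

__all__ = [
    "TEFeature",
    "CoverageTrack",
    "EmissionTrack",
    "read_te_annotations",
    "filter_gypsy",
    "strand_coverage",
    "discretize_emissions",
    "write_bedgraph",
]

DEFAULT_GYPSY_PATTERNS = ("gypsy",)


@dataclass(frozen=True)
class TEFeature:
    """One TE annotation interval, 0-based half-open, strand-resolved."""

    contig: str
    start: int
    end: int
    strand: str
    family_label: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class CoverageTrack:
    """Per-bin fraction covered by selected TEs, one value per strand."""

    grid: BinGrid
    plus_frac: np.ndarray
    minus_frac: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.plus_frac, self.minus_frac):
            if len(arr) != self.grid.n_bins:
                raise ValueError("coverage length does not match bin count")
            if np.any(arr < 0) or np.any(arr > 1 + 1e-12):
                raise ValueError("coverage fractions must lie in [0, 1]")


@dataclass(frozen=True)
class EmissionTrack:
    """Per-bin emission symbol in {0, 1, 2}; the threshold is recorded."""

    grid: BinGrid
    symbols: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if len(self.symbols) != self.grid.n_bins:
            raise ValueError("symbol count does not match bin count")
        if self.symbols.size and not np.isin(self.symbols, (0, 1, 2)).all():
            raise ValueError("emission symbols must be in {0, 1, 2}")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
        elif " " in item:  # loose RepeatMasker-style dialect
            key, value = item.split(None, 1)
            value = value.strip('"')
        else:
            continue
        attrs[key.strip()] = value.strip()
    return attrs


def read_te_annotations(
    path: str | Path,
    format: str | None = None,
    attribute_key: str = "Classification",
) -> list[TEFeature]:
    """Read TE features from BED6 or GFF3, in file order.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    The family label comes from the BED name column, or from the GFF3
    attribute named ``attribute_key`` (default ``Classification``, the EDTA
    convention) with the feature type as fallback. Features without a
    definite strand (``.``) are dropped; the count is logged.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".gff", ".gff3"}:
            format = "gff3"
        elif suffix == ".bed":
            format = "bed6"
        else:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    if format not in {"bed6", "gff3"}:
        raise ValueError(f"unknown annotation format: {format!r}")

    features: list[TEFeature] = []
    n_unstranded = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed6":
                    if len(fields) < 6:
                        raise ValueError("BED6 requires 6 columns")
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    label, strand = fields[3], fields[5]
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 requires 9 columns")
                    contig = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6]
                    attrs = _parse_gff3_attributes(fields[8])
                    label = attrs.get(attribute_key, fields[2])
                if strand not in {"+", "-"}:
                    n_unstranded += 1
                    continue
                features.append(TEFeature(contig, start, end, strand, label))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    if n_unstranded:
        logger.warning(
            "%s: dropped %d feature(s) without a definite strand", path, n_unstranded
        )
    return features


def filter_gypsy(
    features: Sequence[TEFeature],
    patterns: Sequence[str] = DEFAULT_GYPSY_PATTERNS,
    match: str = "substring",
) -> list[TEFeature]:
    """Keep features whose family label matches any pattern.

    ``match='substring'`` (default) is a case-insensitive substring test —
    the default pattern ``'gypsy'`` selects Gypsy-family labels from both
    EDTA (``Gypsy_LTR_retrotransposon``) and RepeatMasker (``LTR/Gypsy``)
    dialects. ``match='exact'`` requires full, case-sensitive equality.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    if match == "substring":
        lowered = [p.lower() for p in patterns]
        return [
            f for f in features if any(p in f.family_label.lower() for p in lowered)
        ]
    if match == "exact":
        wanted = set(patterns)
        return [f for f in features if f.family_label in wanted]
    raise ValueError(f"unknown match mode: {match!r}")


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def strand_coverage(grid: BinGrid, features: Sequence[TEFeature]) -> CoverageTrack:
    """Fraction of each bin covered by features, separately per strand.

    Features are unioned per strand before counting, so overlapping or
    fragmented annotations never push a fraction above 1. Features on
    contigs absent from the grid are dropped with a warning; features
    running past a contig end are clipped.
    """
    name_to_idx = {name: i for i, name in enumerate(grid.contigs.names)}
    covered = {
        "+": np.zeros(grid.n_bins, dtype=np.float64),
        "-": np.zeros(grid.n_bins, dtype=np.float64),
    }
    # group feature intervals by (contig, strand)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_unknown = 0
    for f in features:
        if f.contig not in name_to_idx:
            n_unknown += 1
            continue
        length = grid.contigs.lengths[name_to_idx[f.contig]]
        start, end = f.start, min(f.end, length)
        if start >= end:
            continue
        by_key.setdefault((f.contig, f.strand), []).append((start, end))
    if n_unknown:
        logger.warning("dropped %d feature(s) on contigs absent from the grid", n_unknown)

    bin_size = grid.bin_size
    for (contig, strand), intervals in by_key.items():
        sl = grid.contig_slice(contig)
        offset = sl.start
        ends = grid.ends[sl]
        for s, e in _union_intervals(intervals):
            first = s // bin_size
            last = (e - 1) // bin_size
            for b in range(first, last + 1):
                bin_start = b * bin_size
                bin_end = ends[b]
                covered[strand][offset + b] += min(e, bin_end) - max(s, bin_start)

    widths = grid.widths.astype(np.float64)
    return CoverageTrack(
        grid=grid,
        plus_frac=covered["+"] / widths,
        minus_frac=covered["-"] / widths,
    )


def discretize_emissions(cov: CoverageTrack, threshold: float) -> EmissionTrack:
    """Map the two coverage fractions of each bin to an emission symbol.

    Both strands at or above ``threshold`` gives 2, exactly one gives 1,
    neither gives 0. The comparison is inclusive (>=), so documented
    threshold values are attainable boundaries.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    symbols = (cov.plus_frac >= threshold).astype(np.int64) + (
        cov.minus_frac >= threshold
    ).astype(np.int64)
    return EmissionTrack(grid=cov.grid, symbols=symbols, threshold=float(threshold))


def write_bedgraph(grid: BinGrid, values: np.ndarray, path: str | Path) -> None:
    """Write one value per bin as bedGraph-like TSV (contig, start, end, value)."""
    if len(values) != grid.n_bins:
        raise ValueError("value count does not match bin count")
    with open(path, "w") as fh:
        for ci, s, e, v in zip(grid.contig_index, grid.starts, grid.ends, values):
            fh.write(f"{grid.contigs.names[ci]}\t{s}\t{e}\t{v}\n")
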