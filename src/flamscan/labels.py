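"""Ground-truth state tracks from interval annotations.

Hidden states are per-bin labels: 0 = background, 1 = flam-like cluster,
2 = centromere-like region. Truth tracks are built from BED intervals of
known cluster and centromere regions: a bin takes a non-zero label when a
minimum fraction of it (default one half) overlaps an annotated interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import BinGrid

logger = logging.getLogger(__name__)

__all__ = ["StateTrack", "labels_from_bed", "read_bed_intervals"]

Interval = tuple[str, int, int]


@dataclass(frozen=True)
class StateTrack:
    """Per-bin hidden-state labels on a bin grid.

    ``provenance`` records whether the labels are ground truth or model
    predictions.
    """

    grid: BinGrid
    states: np.ndarray
    provenance: str = "truth"

    def __post_init__(self) -> None:
        if len(self.states) != self.grid.n_bins:
            raise ValueError("state count does not match bin count")
        if self.states.size and not np.isin(self.states, (0, 1, 2)).all():
            raise ValueError("states must be in {0, 1, 2}")


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read BED3+ intervals as (contig, start, end) tuples, in file order."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected BED3+")
            try:
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from None
    return intervals


def _overlap_per_bin(grid: BinGrid, intervals: Sequence[Interval]) -> np.ndarray:
    """Bases of each bin overlapped by the union of the given intervals."""
    name_to_idx = {name: i for i, name in enumerate(grid.contigs.names)}
    overlap = np.zeros(grid.n_bins, dtype=np.float64)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in intervals:
        if contig not in name_to_idx:
            logger.warning("annotation on unknown contig %r skipped", contig)
            continue
        length = grid.contigs.lengths[name_to_idx[contig]]
        if end > length:
            logger.warning(
                "interval %s:%d-%d clipped to contig end %d", contig, start, end, length
            )
            end = length
        if start < end:
            by_contig.setdefault(contig, []).append((start, end))
    bin_size = grid.bin_size
    for contig, ivs in by_contig.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        sl = grid.contig_slice(contig)
        ends = grid.ends[sl]
        for s, e in merged:
            for b in range(s // bin_size, (e - 1) // bin_size + 1):
                overlap[sl.start + b] += min(e, ends[b]) - max(s, b * bin_size)
    return overlap


def labels_from_bed(
    grid: BinGrid,
    cluster_intervals: Sequence[Interval] | str | Path,
    centromere_intervals: Sequence[Interval] | str | Path,
    min_overlap_frac: float = 0.5,
) -> StateTrack:
    """Build a truth :class:`StateTrack` from cluster and centromere intervals.

    A bin is labelled 1 (cluster) or 2 (centromere) when at least
    ``min_overlap_frac`` of its width overlaps the corresponding interval
    set; any other bin is 0. If a bin qualifies for both, the cluster label
    wins and a warning is logged. Interval arguments may be BED paths or
    in-memory (contig, start, end) sequences.
    """
    if isinstance(cluster_intervals, (str, Path)):
        cluster_intervals = read_bed_intervals(cluster_intervals)
    if isinstance(centromere_intervals, (str, Path)):
        centromere_intervals = read_bed_intervals(centromere_intervals)
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    widths = grid.widths.astype(np.float64)
    cluster_hit = _overlap_per_bin(grid, cluster_intervals) / widths >= min_overlap_frac
    centro_hit = _overlap_per_bin(grid, centromere_intervals) / widths >= min_overlap_frac
    both = cluster_hit & centro_hit
    if both.any():
        logger.warning(
            "%d bin(s) matched both cluster and centromere annotations; "
            "cluster label takes precedence",
            int(both.sum()),
        )
    states = np.zeros(grid.n_bins, dtype=np.int64)
    states[centro_hit] = 2
    states[cluster_hit] = 1
    return StateTrack(grid=grid, states=states, provenance="truth")
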