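"""Merge per-bin state predictions into genomic cluster calls.

Maximal runs of identical non-zero state become interval calls; optional
smoothing bridges same-state runs across short background gaps and drops
short runs. Strand is inferred for cluster calls from the TE coverage
asymmetry: unistrand clusters carry Gypsy fragments predominantly
antisense to the piRNA precursor, so the inferred cluster strand is the
opposite of the TE-majority strand. Strand inference is a derived
annotation on top of the model — the emission alphabet is
strand-symmetric, so the HMM itself cannot call strand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import BinGrid
from .labels import StateTrack
from .te import CoverageTrack

__all__ = [
    "ClusterCall",
    "merge_state_runs",
    "assign_cluster_strand",
    "write_calls_bed",
    "read_calls_bed",
    "calls_to_track",
]

_CALL_NAMES = {1: "flam_like", 2: "centromere_like"}
_NAME_TO_STATE = {v: k for k, v in _CALL_NAMES.items()}


@dataclass(frozen=True)
class ClusterCall:
    """A merged run of same-state bins as a genomic interval."""

    contig: str
    start: int
    end: int
    state: int
    n_bins: int
    mean_plus_frac: float = 0.0
    mean_minus_frac: float = 0.0
    te_strand: str = "."
    inferred_cluster_strand: str = "."

    def __post_init__(self) -> None:
        if self.state not in (1, 2):
            raise ValueError("background runs are not emitted as calls")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def merge_state_runs(
    pred: StateTrack, min_bins: int = 1, max_gap_bins: int = 0
) -> list[ClusterCall]:
    """Run-length merge of non-zero states into calls, per contig.

    Runs of the same state separated by at most ``max_gap_bins`` background
    bins are bridged (gap bins count toward the span but not ``n_bins``);
    afterwards, runs with fewer than ``min_bins`` state bins are dropped.
    Calls never cross contig boundaries. Defaults are faithful to the raw
    per-bin output (no smoothing).
    """
    grid = pred.grid
    calls: list[ClusterCall] = []
    for name, sl in grid.iter_contig_slices():
        states = pred.states[sl]
        starts = grid.starts[sl]
        ends = grid.ends[sl]
        # maximal identical-state runs as (state, first_bin, last_bin)
        runs: list[list[int]] = []
        for i, s in enumerate(states):
            if s == 0:
                continue
            if runs and runs[-1][0] == s and runs[-1][2] == i - 1:
                runs[-1][2] = i
                runs[-1][3] += 1
            else:
                runs.append([int(s), i, i, 1])
        # bridge consecutive same-state runs across small background gaps
        bridged: list[list[int]] = []
        for run in runs:
            if (
                bridged
                and bridged[-1][0] == run[0]
                and run[1] - bridged[-1][2] - 1 <= max_gap_bins
            ):
                bridged[-1][2] = run[2]
                bridged[-1][3] += run[3]
            else:
                bridged.append(run)
        for state, first, last, n in bridged:
            if n < min_bins:
                continue
            calls.append(
                ClusterCall(
                    contig=name,
                    start=int(starts[first]),
                    end=int(ends[last]),
                    state=state,
                    n_bins=n,
                )
            )
    return calls


def assign_cluster_strand(call: ClusterCall, cov: CoverageTrack) -> ClusterCall:
    """Annotate a call with TE strand bias and the inferred cluster strand.

    The TE strand is whichever strand has the larger summed coverage over
    the call's bins ('.' on an exact tie). For flam-like calls the cluster
    strand is the opposite; centromere-like calls get '.' on both fields.
    Also fills the mean per-strand coverage fractions.
    """
    grid = cov.grid
    sl = grid.contig_slice(call.contig)
    in_call = (grid.starts[sl] >= call.start) & (grid.ends[sl] <= call.end)
    plus = cov.plus_frac[sl][in_call]
    minus = cov.minus_frac[sl][in_call]
    mean_plus = float(plus.mean()) if len(plus) else 0.0
    mean_minus = float(minus.mean()) if len(minus) else 0.0
    if call.state != 1:
        te_strand, cluster_strand = ".", "."
    elif plus.sum() > minus.sum():
        te_strand, cluster_strand = "+", "-"
    elif minus.sum() > plus.sum():
        te_strand, cluster_strand = "-", "+"
    else:
        te_strand, cluster_strand = ".", "."
    return dataclasses.replace(
        call,
        mean_plus_frac=mean_plus,
        mean_minus_frac=mean_minus,
        te_strand=te_strand,
        inferred_cluster_strand=cluster_strand,
    )


_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tn_bins\tmean_plus_frac\tmean_minus_frac\n"
)


def write_calls_bed(calls: Sequence[ClusterCall], path: str | Path) -> None:
    """Write calls as BED6+3 in deterministic coordinate order.

    score = min(1000, round(1000 * (mean_plus_frac + mean_minus_frac)))
    (per-bin mean TE coverage, both strands, clamped to the BED score
    range); strand = inferred cluster strand.
    """
    ordered = sorted(calls, key=lambda c: (c.contig, c.start, c.end))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER)
        for c in ordered:
            score = min(1000, round(1000 * (c.mean_plus_frac + c.mean_minus_frac)))
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{_CALL_NAMES[c.state]}\t{score}\t"
                f"{c.inferred_cluster_strand}\t{c.n_bins}\t"
                f"{c.mean_plus_frac:.6f}\t{c.mean_minus_frac:.6f}\n"
            )


def read_calls_bed(path: str | Path) -> list[ClusterCall]:
    """Read back a calls BED written by :func:`write_calls_bed`."""
    calls: list[ClusterCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}, line {lineno}: expected 9 columns")
            calls.append(
                ClusterCall(
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    state=_NAME_TO_STATE[f[3]],
                    n_bins=int(f[6]),
                    mean_plus_frac=float(f[7]),
                    mean_minus_frac=float(f[8]),
                    inferred_cluster_strand=f[5],
                )
            )
    return calls


def calls_to_track(calls: Sequence[ClusterCall], grid: BinGrid) -> StateTrack:
    """Expand interval calls back to a per-bin state track (gaps become 0)."""
    states = np.zeros(grid.n_bins, dtype=np.int64)
    for c in calls:
        sl = grid.contig_slice(c.contig)
        in_call = (grid.starts[sl] >= c.start) & (grid.ends[sl] <= c.end)
        states[np.arange(sl.start, sl.stop)[in_call]] = c.state
    return StateTrack(grid=grid, states=states, provenance="predicted")
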