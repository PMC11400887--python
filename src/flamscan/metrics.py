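"""Bin-level classification metrics.

Predictions are scored against truth one-vs-rest per class over genomic
bins: precision = TP/(TP+FP), recall (TPR) = TP/(TP+FN),
FPR = FP/(FP+TN), F1 = 2TP/(2TP+FP+FN). Macro averages are taken over
the classes actually present (classes with TP+FP+FN = 0 are excluded, so
a vacuously absent class cannot inflate the mean). Evaluation can be
restricted to the contigs retained by an NX cut-off (N90 by default),
which suppresses the fragmented, unplaced contigs where false positives
concentrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ContigSet, filter_contigs_by_nx
from .labels import StateTrack

logger = logging.getLogger(__name__)

__all__ = ["ConfusionSummary", "MetricsReport", "confusion", "class_metrics",
           "evaluate_assembly"]

N_CLASSES = 3


@dataclass(frozen=True)
class ConfusionSummary:
    """One-vs-rest bin counts per class: TP, FP, FN, TN arrays of length 3."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        totals = self.tp + self.fp + self.fn + self.tn
        if np.any(totals != self.n_bins):
            raise ValueError("TP+FP+FN+TN must equal n_bins for every class")


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged metrics.

    ``included_classes`` lists the classes entering the macro means
    (those with TP+FP+FN > 0). FPR is reported per class only; the
    headline user-facing FPR is class 1 (flam-like cluster predictions).
    """

    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    included_classes: tuple[int, ...]
    counts: ConfusionSummary = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "precision": self.precision[c],
                "recall": self.recall[c],
                "fpr": self.fpr[c],
                "f1": self.f1[c],
                "tp": int(self.counts.tp[c]),
                "fp": int(self.counts.fp[c]),
                "fn": int(self.counts.fn[c]),
                "tn": int(self.counts.tn[c]),
            }
            for c in range(N_CLASSES)
        ]
        rows.append(
            {
                "class": "macro",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "fpr": float("nan"),
                "f1": self.macro_f1,
                "tp": int(self.counts.tp.sum()),
                "fp": int(self.counts.fp.sum()),
                "fn": int(self.counts.fn.sum()),
                "tn": int(self.counts.tn.sum()),
            }
        )
        return pd.DataFrame(rows)


def confusion(truth: StateTrack, pred: StateTrack) -> ConfusionSummary:
    """One-vs-rest confusion counts over bins; tracks must share a grid."""
    if truth.grid.n_bins != pred.grid.n_bins or not (
        np.array_equal(truth.grid.starts, pred.grid.starts)
        and np.array_equal(truth.grid.contig_index, pred.grid.contig_index)
    ):
        raise ValueError("truth and prediction tracks are on different grids")
    t, p = truth.states, pred.states
    n = len(t)
    tp = np.empty(N_CLASSES, dtype=np.int64)
    fp = np.empty(N_CLASSES, dtype=np.int64)
    fn = np.empty(N_CLASSES, dtype=np.int64)
    for c in range(N_CLASSES):
        tp[c] = int(np.sum((t == c) & (p == c)))
        fp[c] = int(np.sum((t != c) & (p == c)))
        fn[c] = int(np.sum((t == c) & (p != c)))
    tn = n - tp - fp - fn
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn, n_bins=n)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise division with the 0/0 -> 0 convention."""
    out = np.zeros_like(num, dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def class_metrics(cs: ConfusionSummary) -> MetricsReport:
    """Per-class precision/recall/FPR/F1 and macro means over present classes."""
    precision = _safe_div(cs.tp, cs.tp + cs.fp)
    recall = _safe_div(cs.tp, cs.tp + cs.fn)
    fpr = _safe_div(cs.fp, cs.fp + cs.tn)
    f1 = _safe_div(2 * cs.tp, 2 * cs.tp + cs.fp + cs.fn)
    included = tuple(
        c for c in range(N_CLASSES) if cs.tp[c] + cs.fp[c] + cs.fn[c] > 0
    )
    if len(included) < N_CLASSES:
        logger.info(
            "classes %s absent from both truth and predictions; excluded from "
            "macro averages",
            sorted(set(range(N_CLASSES)) - set(included)),
        )
    idx = list(included)
    return MetricsReport(
        precision=precision,
        recall=recall,
        fpr=fpr,
        f1=f1,
        macro_precision=float(precision[idx].mean()) if idx else 0.0,
        macro_recall=float(recall[idx].mean()) if idx else 0.0,
        macro_f1=float(f1[idx].mean()) if idx else 0.0,
        included_classes=included,
        counts=cs,
    )


def evaluate_assembly(
    truth: StateTrack,
    pred: StateTrack,
    contigs: ContigSet | None = None,
    nx: float = 90,
) -> MetricsReport:
    """Metrics restricted to bins on contigs retained by the NX cut-off.

    ``nx=100`` keeps every contig, reproducing the unfiltered metrics.
    """
    if contigs is None:
        contigs = truth.grid.contigs
    kept = set(filter_contigs_by_nx(contigs, nx).names)
    grid = truth.grid
    mask = np.array([grid.contigs.names[i] in kept for i in grid.contig_index])
    if not mask.any():
        raise ValueError(f"no bins survive the N{nx:g} contig filter")
    # restricted tracks live on a masked-down copy of the grid
    from .genome import BinGrid

    sub_grid = BinGrid(
        contigs=grid.contigs,
        bin_size=grid.bin_size,
        contig_index=grid.contig_index[mask],
        starts=grid.starts[mask],
        ends=grid.ends[mask],
    )
    t = StateTrack(grid=sub_grid, states=truth.states[mask], provenance=truth.provenance)
    p = StateTrack(grid=sub_grid, states=pred.states[mask], provenance=pred.provenance)
    return class_metrics(confusion(t, p))
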