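"""Leave-one-species-out cross-validation over bin sizes and thresholds.

For every (bin_size, threshold) setting and every held-out species, one
model is fitted per training species and the per-species models are
combined as their arithmetic mean; the combined model decodes the
held-out species, and bin-level metrics are computed on its N90 contigs.
Settings are ranked by the median macro-F1 across folds, ties broken
toward the lower threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genome import ContigSet, make_bins
from .hmm import HMMParams, LabeledTrack, average_models, fit_supervised, viterbi_decode
from .labels import Interval, StateTrack, labels_from_bed
from .metrics import MetricsReport, evaluate_assembly
from .te import (
    CoverageTrack,
    EmissionTrack,
    TEFeature,
    discretize_emissions,
    filter_gypsy,
    strand_coverage,
)

logger = logging.getLogger(__name__)

__all__ = ["SpeciesData", "build_labeled_track", "train_combined",
           "cross_validate", "rank_settings"]


@dataclass(frozen=True)
class SpeciesData:
    """Raw per-species inputs: contigs, TE features and truth intervals."""

    species_id: str
    contigs: ContigSet
    features: list[TEFeature] = field(repr=False)
    cluster_intervals: list[Interval] = field(repr=False)
    centromere_intervals: list[Interval] = field(repr=False)


def build_labeled_track(
    species: SpeciesData,
    bin_size: int,
    threshold: float,
    min_overlap_frac: float = 0.5,
    already_filtered: bool = False,
) -> tuple[LabeledTrack, CoverageTrack]:
    """Bin a species' genome and derive its emission and truth state tracks."""
    grid = make_bins(species.contigs, bin_size)
    feats = species.features if already_filtered else filter_gypsy(species.features)
    cov = strand_coverage(grid, feats)
    emissions = discretize_emissions(cov, threshold)
    truth = labels_from_bed(
        grid,
        species.cluster_intervals,
        species.centromere_intervals,
        min_overlap_frac=min_overlap_frac,
    )
    track = LabeledTrack(
        grid=grid,
        states=truth.states,
        emissions=emissions.symbols,
        species_id=species.species_id,
    )
    return track, cov


def train_combined(
    tracks: Sequence[LabeledTrack], bin_size: int, threshold: float
) -> HMMParams:
    """Fit one model per species track and combine as their mean."""
    meta = {"bin_size": int(bin_size), "threshold": float(threshold)}
    models = [fit_supervised([t], metadata=meta) for t in tracks]
    return average_models(models)


def cross_validate(
    corpus: Sequence[SpeciesData],
    bin_sizes: Sequence[int] = (2500, 5000, 10000),
    thresholds: Sequence[float] = (0.025, 0.05, 0.075, 0.1),
    nx: float = 90,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Leave-one-out cross-validation table.

    Returns one row per (bin_size, threshold, held-out species) with
    macro precision/recall/F1 and the class-1 (cluster) recall and FPR.
    Deterministic given the inputs: training and decoding involve no
    randomness.
    """
    if len(corpus) < 2:
        raise ValueError("cross-validation requires at least 2 species")
    rows = []
    for bin_size in bin_sizes:
        for threshold in thresholds:
            tracks = {
                sp.species_id: build_labeled_track(
                    sp, bin_size, threshold, min_overlap_frac
                )[0]
                for sp in corpus
            }
            for held_out in corpus:
                train_tracks = [
                    tracks[sp.species_id]
                    for sp in corpus
                    if sp.species_id != held_out.species_id
                ]
                model = train_combined(train_tracks, bin_size, threshold)
                test_track = tracks[held_out.species_id]
                pred = viterbi_decode(
                    model,
                    EmissionTrack(
                        grid=test_track.grid,
                        symbols=test_track.emissions,
                        threshold=threshold,
                    ),
                )
                truth = StateTrack(
                    grid=test_track.grid, states=test_track.states, provenance="truth"
                )
                report = evaluate_assembly(truth, pred, held_out.contigs, nx=nx)
                rows.append(
                    {
                        "bin_size": int(bin_size),
                        "threshold": float(threshold),
                        "held_out": held_out.species_id,
                        "macro_precision": report.macro_precision,
                        "macro_recall": report.macro_recall,
                        "macro_f1": report.macro_f1,
                        "cluster_recall": report.recall[1],
                        "cluster_fpr": report.fpr[1],
                    }
                )
            logger.info("cross-validated bin_size=%d threshold=%g", bin_size, threshold)
    return pd.DataFrame(rows)


def rank_settings(cv_table: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Rank (bin_size, threshold) settings by median macro-F1 across folds.

    Ties are broken toward the lower threshold, then the smaller bin size;
    the ordering is fully deterministic.
    """
    med = (
        cv_table.groupby(["bin_size", "threshold"], as_index=False)
        .agg(median_macro_f1=("macro_f1", "median"))
        .sort_values(
            ["median_macro_f1", "threshold", "bin_size"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )
    med.insert(0, "rank", med.index + 1)
    return med.head(top_k) if top_k else med
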