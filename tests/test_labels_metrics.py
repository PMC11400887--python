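"""Truth-track construction and bin-level evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flamscan import (
    ConfusionSummary,
    ContigSet,
    StateTrack,
    class_metrics,
    confusion,
    evaluate_assembly,
    labels_from_bed,
    make_bins,
)


def _grid(entries, bin_size=5000):
    return make_bins(ContigSet.from_entries(entries), bin_size)


def _summary(tp, fp, fn, n_bins, cls=1):
    arr = lambda v: np.array(v, dtype=np.int64)
    tps, fps, fns = arr([0, 0, 0]), arr([0, 0, 0]), arr([0, 0, 0])
    tps[cls], fps[cls], fns[cls] = tp, fp, fn
    tns = n_bins - tps - fps - fns
    return ConfusionSummary(tp=tps, fp=fps, fn=fns, tn=tns, n_bins=n_bins)


class TestLabelsFromBed:
    def test_bin_inside_cluster_is_state_1(self):
        grid = _grid([("c1", 20000)])
        track = labels_from_bed(grid, [("c1", 0, 20000)], [])
        assert (track.states == 1).all()

    def test_overlap_below_half_stays_background(self):
        grid = _grid([("c1", 10000)])
        # second bin overlaps the cluster by 2 kb of 5 kb
        track = labels_from_bed(grid, [("c1", 0, 7000)], [])
        assert track.states.tolist() == [1, 0]

    def test_no_annotations_all_zero(self):
        track = labels_from_bed(_grid([("c1", 20000)]), [], [])
        assert not track.states.any()

    def test_centromere_bins_are_state_2(self):
        grid = _grid([("c1", 20000)])
        track = labels_from_bed(grid, [], [("c1", 5000, 15000)])
        assert track.states.tolist() == [0, 2, 2, 0]

    def test_cluster_wins_over_centromere_with_warning(self, caplog):
        grid = _grid([("c1", 10000)])
        with caplog.at_level("WARNING"):
            track = labels_from_bed(grid, [("c1", 0, 10000)], [("c1", 0, 10000)])
        assert (track.states == 1).all()
        assert "precedence" in caplog.text

    def test_interval_past_contig_end_clipped(self, caplog):
        grid = _grid([("c1", 10000)])
        with caplog.at_level("WARNING"):
            track = labels_from_bed(grid, [("c1", 5000, 99000)], [])
        assert track.states.tolist() == [0, 1]
        assert "clipped" in caplog.text


class TestConfusion:
    def test_perfect_agreement(self):
        grid = _grid([("c1", 20000)])
        t = StateTrack(grid=grid, states=np.array([0, 1, 2, 1]))
        cs = confusion(t, t)
        assert not cs.fp.any() and not cs.fn.any()

    def test_hand_counts_for_class_1(self):
        grid = _grid([("c1", 20000)])
        t = StateTrack(grid=grid, states=np.array([1, 1, 0, 0]))
        p = StateTrack(grid=grid, states=np.array([1, 0, 1, 0]), provenance="predicted")
        cs = confusion(t, p)
        assert (cs.tp[1], cs.fn[1], cs.fp[1], cs.tn[1]) == (1, 1, 1, 1)

    def test_all_wrong(self):
        grid = _grid([("c1", 20000)])
        t = StateTrack(grid=grid, states=np.zeros(4, dtype=int))
        p = StateTrack(grid=grid, states=np.ones(4, dtype=int), provenance="predicted")
        cs = confusion(t, p)
        assert (cs.tp[1], cs.fp[1], cs.fn[1], cs.tn[1]) == (0, 4, 0, 0)

    def test_grid_mismatch_rejected(self):
        t = StateTrack(grid=_grid([("c1", 20000)]), states=np.zeros(4, dtype=int))
        p = StateTrack(grid=_grid([("c2", 20000)], 10000), states=np.zeros(2, dtype=int))
        with pytest.raises(ValueError):
            confusion(t, p)

    def test_diagonal_sum_equals_correct_bins(self):
        rng = np.random.default_rng(4)
        grid = _grid([("c1", 5000 * 60)])
        t = StateTrack(grid=grid, states=rng.integers(0, 3, 60))
        p = StateTrack(grid=grid, states=rng.integers(0, 3, 60), provenance="predicted")
        cs = confusion(t, p)
        assert cs.tp.sum() == int((t.states == p.states).sum())


class TestClassMetrics:
    def test_symmetric_counts(self):
        rep = class_metrics(_summary(tp=2, fp=1, fn=1, n_bins=10))
        assert rep.precision[1] == pytest.approx(2 / 3)
        assert rep.recall[1] == pytest.approx(2 / 3)
        assert rep.f1[1] == pytest.approx(2 / 3)

    def test_f1_harmonic_identity(self):
        rep = class_metrics(_summary(tp=2, fp=2, fn=0, n_bins=10))
        assert rep.precision[1] == pytest.approx(0.5)
        assert rep.recall[1] == pytest.approx(1.0)
        assert rep.f1[1] == pytest.approx(2 / 3)

    def test_degenerate_zero_over_zero_is_zero(self):
        rep = class_metrics(_summary(tp=0, fp=0, fn=3, n_bins=10))
        assert rep.precision[1] == 0 and rep.recall[1] == 0 and rep.f1[1] == 0

    def test_absent_classes_excluded_from_macro(self):
        # only class 0 present: truth and predictions all background
        cs = ConfusionSummary(
            tp=np.array([5, 0, 0]), fp=np.zeros(3, dtype=int),
            fn=np.zeros(3, dtype=int), tn=np.array([0, 5, 5]), n_bins=5,
        )
        rep = class_metrics(cs)
        assert rep.included_classes == (0,)
        assert rep.macro_f1 == 1.0

    @given(st.data())
    def test_count_form_equals_harmonic_form(self, data):
        tp = data.draw(st.integers(0, 50))
        fp = data.draw(st.integers(0, 50))
        fn = data.draw(st.integers(0, 50))
        rep = class_metrics(_summary(tp, fp, fn, n_bins=tp + fp + fn + 10))
        p, r = rep.precision[1], rep.recall[1]
        harmonic = 2 * p * r / (p + r) if p + r > 0 else 0.0
        assert abs(rep.f1[1] - harmonic) < 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        grid = _grid([("c1", 5000 * 40)])
        t = rng.integers(0, 3, 40)
        p = rng.integers(0, 3, 40)
        perm = rng.permutation(40)
        rep1 = class_metrics(confusion(
            StateTrack(grid=grid, states=t),
            StateTrack(grid=grid, states=p, provenance="predicted")))
        rep2 = class_metrics(confusion(
            StateTrack(grid=grid, states=t[perm]),
            StateTrack(grid=grid, states=p[perm], provenance="predicted")))
        assert rep1.macro_f1 == rep2.macro_f1


class TestEvaluateAssembly:
    def test_nx100_equals_unfiltered(self):
        contigs = ContigSet.from_entries([("big", 50000), ("tiny", 5000)])
        grid = make_bins(contigs, 5000)
        rng = np.random.default_rng(1)
        t = StateTrack(grid=grid, states=rng.integers(0, 3, grid.n_bins))
        p = StateTrack(grid=grid, states=rng.integers(0, 3, grid.n_bins),
                       provenance="predicted")
        full = class_metrics(confusion(t, p))
        assert evaluate_assembly(t, p, contigs, nx=100).macro_f1 == full.macro_f1

    def test_disagreement_on_sub_n90_contig_is_invisible(self):
        contigs = ContigSet.from_entries([("big", 100_000), ("tiny", 5000)])
        grid = make_bins(contigs, 5000)
        states = np.zeros(grid.n_bins, dtype=int)
        states[:5] = 1
        truth = StateTrack(grid=grid, states=states)
        wrong = states.copy()
        wrong[-1] = 1  # error confined to the tiny contig
        pred = StateTrack(grid=grid, states=wrong, provenance="predicted")
        rep = evaluate_assembly(truth, pred, contigs, nx=90)
        assert rep.macro_f1 == 1.0

    def test_retained_bin_conservation(self):
        contigs = ContigSet.from_entries([("big", 100_000), ("tiny", 5000)])
        grid = make_bins(contigs, 5000)
        rng = np.random.default_rng(2)
        t = StateTrack(grid=grid, states=rng.integers(0, 3, grid.n_bins))
        p = StateTrack(grid=grid, states=rng.integers(0, 3, grid.n_bins),
                       provenance="predicted")
        rep = evaluate_assembly(t, p, contigs, nx=90)
        assert (rep.counts.tp + rep.counts.fn).sum() == 20  # bins on 'big' only
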