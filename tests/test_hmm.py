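"""Supervised MLE, model averaging, Viterbi decoding and sampling."""

import numpy as np
import pytest

from flamscan import (
    ContigSet,
    EmissionTrack,
    HMMParams,
    LabeledTrack,
    SupervisedCategoricalHMM,
    average_models,
    fit_supervised,
    load_params,
    load_pretrained,
    make_bins,
    posterior_marginals,
    sample_path,
    save_params,
    viterbi_decode,
)

from _oracles import mle_oracle, path_logprob, random_hmm_params, viterbi_oracle


def _track(states, emissions, bin_size=1000, species="sp"):
    states = np.asarray(states)
    grid = make_bins(ContigSet.from_entries([("c1", bin_size * len(states))]), bin_size)
    return LabeledTrack(grid=grid, states=states, emissions=np.asarray(emissions),
                        species_id=species)


def _params(pi, a, b, **meta):
    return HMMParams(startprob=np.asarray(pi), transmat=np.asarray(a),
                     emissionprob=np.asarray(b), metadata=meta)


class TestFitSupervised:
    def test_hand_worked_transition_pseudocounts(self):
        track = _track([0, 0, 1, 1, 1, 0], [0] * 6)
        params = fit_supervised([track])
        row0 = np.array([1.001, 1.001, 0.001]) / 2.003
        row1 = np.array([1.001, 2.001, 0.001]) / 3.003
        row2 = np.array([0.001, 0.001, 0.001]) / 0.003
        np.testing.assert_allclose(params.transmat[0], row0, atol=1e-12)
        np.testing.assert_allclose(params.transmat[1], row1, atol=1e-12)
        np.testing.assert_allclose(params.transmat[2], row2, atol=1e-12)

    def test_hand_worked_emission_pseudocounts(self):
        params = fit_supervised([_track([0, 0, 1, 1, 1, 0], [0] * 6)])
        np.testing.assert_allclose(params.emissionprob[0], np.array([4, 1, 1]) / 6,
                                   atol=1e-12)
        np.testing.assert_allclose(params.emissionprob[1], np.array([4, 1, 1]) / 6,
                                   atol=1e-12)

    def test_one_start_observation_per_contig(self):
        grid = make_bins(ContigSet.from_entries([("c1", 3000), ("c2", 2000)]), 1000)
        track = LabeledTrack(grid=grid, states=np.array([0, 0, 0, 2, 2]),
                             emissions=np.zeros(5, dtype=int))
        params = fit_supervised([track])
        np.testing.assert_allclose(params.startprob, np.array([2, 1, 2]) / 5, atol=1e-12)

    def test_transitions_do_not_cross_contigs(self):
        grid = make_bins(ContigSet.from_entries([("c1", 2000), ("c2", 2000)]), 1000)
        track = LabeledTrack(grid=grid, states=np.array([1, 1, 2, 2]),
                             emissions=np.zeros(4, dtype=int))
        params = fit_supervised([track])
        # no 1->2 transition is counted across the contig boundary
        assert params.transmat[1, 2] == pytest.approx(0.001 / 1.003)

    def test_matches_count_oracle_on_random_tracks(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 40))
            states = rng.integers(0, 3, n)
            emissions = rng.integers(0, 3, n)
            params = fit_supervised([_track(states, emissions)])
            pi, a, b = mle_oracle([(states, emissions)])
            np.testing.assert_allclose(params.startprob, pi, atol=1e-12)
            np.testing.assert_allclose(params.transmat, a, atol=1e-12)
            np.testing.assert_allclose(params.emissionprob, b, atol=1e-12)

    def test_rows_stochastic_and_strictly_positive(self):
        params = fit_supervised([_track([0, 1, 2, 1, 0], [0, 1, 2, 2, 0])])
        assert (params.startprob > 0).all()
        assert (params.transmat > 0).all() and (params.emissionprob > 0).all()
        np.testing.assert_allclose(params.transmat.sum(1), 1, atol=1e-9)
        np.testing.assert_allclose(params.emissionprob.sum(1), 1, atol=1e-9)

    def test_empty_tracks_rejected(self):
        with pytest.raises(ValueError):
            fit_supervised([])

    def test_mismatched_lengths_rejected(self):
        grid = make_bins(ContigSet.from_entries([("c1", 3000)]), 1000)
        with pytest.raises(ValueError):
            LabeledTrack(grid=grid, states=np.array([0, 1, 2]),
                         emissions=np.array([0, 1]))


class TestAverageModels:
    def test_identity_for_single_model(self):
        m = fit_supervised([_track([0, 1, 1, 0], [0, 1, 1, 0])])
        avg = average_models([m])
        np.testing.assert_allclose(avg.transmat, m.transmat, atol=1e-12)

    def test_elementwise_mean(self):
        a1 = [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]
        a2 = [[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]]
        b = [[0.9, 0.05, 0.05]] * 3
        m1 = _params([0.5, 0.25, 0.25], a1, b)
        m2 = _params([0.5, 0.25, 0.25], a2, b)
        avg = average_models([m1, m2])
        np.testing.assert_allclose(avg.transmat[0], [0.7, 0.15, 0.15], atol=1e-12)

    def test_mean_rows_are_stochastic(self):
        rng = np.random.default_rng(0)
        models = [_params(*random_hmm_params(rng)) for _ in range(5)]
        avg = average_models(models)
        np.testing.assert_allclose(avg.transmat.sum(1), 1, atol=1e-12)
        np.testing.assert_allclose(avg.emissionprob.sum(1), 1, atol=1e-12)

    def test_mismatched_metadata_rejected(self):
        rng = np.random.default_rng(1)
        m1 = _params(*random_hmm_params(rng), bin_size=5000)
        m2 = _params(*random_hmm_params(rng), bin_size=10000)
        with pytest.raises(ValueError, match="bin_size"):
            average_models([m1, m2])


class TestViterbiDecode:
    def test_near_identity_emissions_copy_the_sequence(self):
        eps = 1e-6
        b = np.full((3, 3), eps)
        np.fill_diagonal(b, 1 - 2 * eps)
        a = np.full((3, 3), 0.1)
        np.fill_diagonal(a, 0.8)
        params = _params([1 / 3] * 3, a, b)
        symbols = np.array([0, 1, 2, 2, 1, 0, 0, 2])
        grid = make_bins(ContigSet.from_entries([("c", 8000)]), 1000)
        track = viterbi_decode(params, EmissionTrack(grid=grid, symbols=symbols,
                                                     threshold=0.075))
        np.testing.assert_array_equal(track.states, symbols)

    def test_length_one_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pi, a, b = random_hmm_params(rng)
            s = int(rng.integers(3))
            est = SupervisedCategoricalHMM().set_model_params(pi, a, b)
            assert est.predict(np.array([s]))[0] == np.argmax(pi * b[:, s])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            pi, a, b = random_hmm_params(rng)
            n = int(rng.integers(1, 7))
            symbols = rng.integers(0, 3, n)
            est = SupervisedCategoricalHMM().set_model_params(pi, a, b)
            decoded = est.predict(symbols)
            _, best_lp = viterbi_oracle(pi, a, b, symbols)
            assert path_logprob(pi, a, b, symbols, decoded) == pytest.approx(
                best_lp, abs=1e-10
            )

    def test_agrees_with_hmmlearn(self):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(23)
        for _ in range(20):
            pi, a, b = random_hmm_params(rng)
            symbols = rng.integers(0, 3, int(rng.integers(5, 60)))
            est = SupervisedCategoricalHMM().set_model_params(pi, a, b)
            ref = hmmlearn_hmm.CategoricalHMM(n_components=3)
            ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, a, b
            ours = est.predict(symbols)
            theirs = ref.predict(symbols.reshape(-1, 1))
            # tie-breaking may differ; the decoded paths must be equally likely
            assert path_logprob(pi, a, b, symbols, ours) == pytest.approx(
                path_logprob(pi, a, b, symbols, theirs), abs=1e-9
            )

    def test_contigs_decoded_independently(self):
        rng = np.random.default_rng(7)
        pi, a, b = random_hmm_params(rng)
        est = SupervisedCategoricalHMM().set_model_params(pi, a, b)
        x1, x2 = rng.integers(0, 3, 30), rng.integers(0, 3, 20)
        joint = est.predict(np.concatenate([x1, x2]), lengths=[30, 20])
        swapped = est.predict(np.concatenate([x2, x1]), lengths=[20, 30])
        np.testing.assert_array_equal(joint[:30], swapped[20:])
        np.testing.assert_array_equal(joint[30:], swapped[:20])

    def test_symbol_outside_alphabet_rejected(self):
        rng = np.random.default_rng(2)
        est = SupervisedCategoricalHMM().set_model_params(*random_hmm_params(rng))
        with pytest.raises(ValueError):
            est.predict(np.array([0, 3]))


class TestPosteriorAndSampling:
    def test_posteriors_sum_to_one(self, trained_model):
        grid = make_bins(ContigSet.from_entries([("c", 50_000)]), 5000)
        symbols = np.array([0, 0, 1, 1, 1, 0, 2, 2, 1, 0])
        gamma = posterior_marginals(
            trained_model, EmissionTrack(grid=grid, symbols=symbols, threshold=0.075)
        )
        np.testing.assert_allclose(gamma.sum(axis=1), 1, atol=1e-9)
        assert gamma.shape == (10, 3)

    def test_degenerate_chain_is_constant(self):
        eps = 1e-12
        pi = np.array([1 - 2 * eps, eps, eps])
        a = np.full((3, 3), eps)
        np.fill_diagonal(a, 1 - 2 * eps)
        params = _params(pi, a, a.copy())
        (states, emissions), = sample_path(params, [50], seed=0)
        assert not states.any() and not emissions.any()

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(9)
        params = _params(*random_hmm_params(rng))
        first = sample_path(params, [100, 37], seed=123)
        second = sample_path(params, [100, 37], seed=123)
        for (s1, e1), (s2, e2) in zip(first, second):
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(e1, e2)

    def test_empirical_transition_frequencies_approach_matrix(self):
        a = np.array([[0.90, 0.07, 0.03], [0.10, 0.85, 0.05], [0.05, 0.10, 0.85]])
        params = _params([0.4, 0.3, 0.3], a,
                         [[0.7, 0.2, 0.1], [0.2, 0.7, 0.1], [0.1, 0.2, 0.7]])
        (states, _), = sample_path(params, [100_000], seed=42)
        for i in range(3):
            mask = states[:-1] == i
            freqs = np.bincount(states[1:][mask], minlength=3) / mask.sum()
            np.testing.assert_allclose(freqs, a[i], atol=0.01)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, trained_model):
        path = tmp_path / "params.json"
        save_params(trained_model, path)
        loaded = load_params(path)
        np.testing.assert_allclose(loaded.transmat, trained_model.transmat, atol=0)
        assert loaded.metadata["bin_size"] == 5000

    def test_bundled_parameters_load_and_validate(self):
        params = load_pretrained(5000, 0.075)
        np.testing.assert_allclose(params.transmat.sum(1), 1, atol=1e-9)
        assert params.metadata["threshold"] == 0.075

    def test_missing_bundle_lists_alternatives(self):
        with pytest.raises(FileNotFoundError, match="available"):
            load_pretrained(1234, 0.5)
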