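"""Categorical hidden Markov model for genome-bin segmentation.

A 3-state, 3-symbol HMM: hidden states are background (0), flam-like
cluster (1) and centromere-like region (2); observed symbols are the
discretised strand-resolved Gypsy TE content of each bin (0 = neither
strand, 1 = one strand, 2 = both strands above threshold).

Training is supervised maximum likelihood with additive pseudocounts —
0.001 for transitions, 1 for emissions and start probabilities — counted
over labelled bins, with each contig forming an independent observation
sequence (transitions never cross contig boundaries and each contig
contributes one start observation). Models trained on several species are
combined as the element-wise arithmetic mean of the per-species models.
Decoding is Viterbi (maximum a-posteriori joint path) in natural-log
space; posterior state marginals are available for diagnostics.

The estimator follows scikit-learn conventions (``fit``/``predict``/
``predict_proba``/``sample``, fitted attributes with a trailing
underscore); the module-level functions are thin wrappers that operate on
the pipeline's track types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .genome import BinGrid
from .labels import StateTrack
from .te import EmissionTrack

__all__ = [
    "SupervisedCategoricalHMM",
    "HMMParams",
    "LabeledTrack",
    "fit_supervised",
    "average_models",
    "viterbi_decode",
    "posterior_marginals",
    "sample_path",
    "save_params",
    "load_params",
    "load_pretrained",
]

_ROW_SUM_TOL = 1e-9

# states
STATE_NONE, STATE_CLUSTER, STATE_CENTROMERE = 0, 1, 2
STATE_NAMES = ("none", "flam_like", "centromere_like")


def _check_sequences(X, lengths, n_symbols):
    X = np.asarray(X, dtype=np.int64).ravel()
    if lengths is None:
        lengths = [len(X)]
    lengths = [int(l) for l in lengths]
    if any(l < 1 for l in lengths):
        raise ValueError("sequence lengths must be >= 1")
    if sum(lengths) != len(X):
        raise ValueError(f"lengths sum to {sum(lengths)} but X has {len(X)} samples")
    if len(X) and (X.min() < 0 or X.max() >= n_symbols):
        raise ValueError(f"symbols must lie in [0, {n_symbols})")
    return X, lengths


class SupervisedCategoricalHMM(BaseEstimator):
    """Discrete-emission HMM trained from fully labelled sequences.

    Parameters
    ----------
    n_states, n_symbols : int
        Sizes of the hidden-state and emission alphabets (both 3 for the
        cluster-annotation model).
    pseudocount_transition, pseudocount_emission, pseudocount_start : float
        Additive pseudocounts applied per matrix cell before row
        normalisation. Positive pseudocounts guarantee strictly positive,
        row-stochastic parameter matrices.

    Attributes
    ----------
    startprob_ : ndarray of shape (n_states,)
        Initial state distribution, one observation per training sequence.
    transmat_ : ndarray of shape (n_states, n_states)
        Row-stochastic transition matrix.
    emissionprob_ : ndarray of shape (n_states, n_symbols)
        Row-stochastic emission matrix.
    """

    def __init__(
        self,
        n_states: int = 3,
        n_symbols: int = 3,
        pseudocount_transition: float = 0.001,
        pseudocount_emission: float = 1.0,
        pseudocount_start: float = 1.0,
    ):
        self.n_states = n_states
        self.n_symbols = n_symbols
        self.pseudocount_transition = pseudocount_transition
        self.pseudocount_emission = pseudocount_emission
        self.pseudocount_start = pseudocount_start

    # -- training -----------------------------------------------------

    def fit(self, X, y, lengths: Sequence[int] | None = None):
        """Estimate start, transition and emission probabilities by MLE.

        ``X`` holds emission symbols and ``y`` the corresponding hidden
        states, concatenated over sequences; ``lengths`` delimits the
        independent sequences (one per contig). Counts are accumulated per
        sequence, the pseudocount is added to every cell, and rows are
        normalised by their own (pseudocounted) sums.
        """
        X, lengths = _check_sequences(X, lengths, self.n_symbols)
        y = np.asarray(y, dtype=np.int64).ravel()
        if len(y) != len(X):
            raise ValueError(f"X has {len(X)} samples but y has {len(y)}")
        if len(y) == 0:
            raise ValueError("cannot fit on empty data")
        if y.min() < 0 or y.max() >= self.n_states:
            raise ValueError(f"states must lie in [0, {self.n_states})")

        start_counts = np.zeros(self.n_states)
        trans_counts = np.zeros((self.n_states, self.n_states))
        emis_counts = np.zeros((self.n_states, self.n_symbols))
        np.add.at(emis_counts, (y, X), 1.0)
        pos = 0
        for length in lengths:
            seq = y[pos : pos + length]
            start_counts[seq[0]] += 1
            np.add.at(trans_counts, (seq[:-1], seq[1:]), 1.0)
            pos += length

        start = start_counts + self.pseudocount_start
        trans = trans_counts + self.pseudocount_transition
        emis = emis_counts + self.pseudocount_emission
        self.startprob_ = start / start.sum()
        self.transmat_ = trans / trans.sum(axis=1, keepdims=True)
        self.emissionprob_ = emis / emis.sum(axis=1, keepdims=True)
        self.n_features_in_ = 1
        return self

    # -- decoding -----------------------------------------------------

    def predict(self, X, lengths: Sequence[int] | None = None) -> np.ndarray:
        """Viterbi state path, decoded independently per sequence.

        Computed in natural-log space. Ties at the traceback are broken
        toward the lower state index, biasing toward the background state.
        """
        self._check_fitted()
        X, lengths = _check_sequences(X, lengths, self.n_symbols)
        out = np.empty(len(X), dtype=np.int64)
        pos = 0
        for length in lengths:
            out[pos : pos + length] = self._viterbi_one(X[pos : pos + length])
            pos += length
        return out

    def _viterbi_one(self, x: np.ndarray) -> np.ndarray:
        log_pi = np.log(self.startprob_)
        log_a = np.log(self.transmat_)
        log_b = np.log(self.emissionprob_)
        n = len(x)
        delta = np.empty((n, self.n_states))
        psi = np.zeros((n, self.n_states), dtype=np.int64)
        delta[0] = log_pi + log_b[:, x[0]]
        for t in range(1, n):
            scores = delta[t - 1][:, None] + log_a  # (from, to)
            psi[t] = np.argmax(scores, axis=0)  # ties -> lowest from-state
            delta[t] = scores[psi[t], np.arange(self.n_states)] + log_b[:, x[t]]
        path = np.empty(n, dtype=np.int64)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(n - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        return path

    def predict_proba(self, X, lengths: Sequence[int] | None = None) -> np.ndarray:
        """Posterior state marginals P(state_t | sequence), forward-backward."""
        self._check_fitted()
        X, lengths = _check_sequences(X, lengths, self.n_symbols)
        out = np.empty((len(X), self.n_states))
        pos = 0
        for length in lengths:
            out[pos : pos + length] = self._forward_backward(X[pos : pos + length])[0]
            pos += length
        return out

    def _forward_backward(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        n = len(x)
        a, b, pi = self.transmat_, self.emissionprob_, self.startprob_
        alpha = np.empty((n, self.n_states))
        scale = np.empty(n)
        alpha[0] = pi * b[:, x[0]]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, n):
            alpha[t] = (alpha[t - 1] @ a) * b[:, x[t]]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.ones((n, self.n_states))
        for t in range(n - 2, -1, -1):
            beta[t] = (a @ (b[:, x[t + 1]] * beta[t + 1])) / scale[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        return gamma, float(np.log(scale).sum())

    def score(self, X, lengths: Sequence[int] | None = None) -> float:
        """Total log-likelihood of the sequences under the model."""
        self._check_fitted()
        X, lengths = _check_sequences(X, lengths, self.n_symbols)
        total = 0.0
        pos = 0
        for length in lengths:
            total += self._forward_backward(X[pos : pos + length])[1]
            pos += length
        return total

    # -- sampling -----------------------------------------------------

    def sample(
        self, lengths: Sequence[int], random_state: int | np.random.Generator
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Draw (states, emissions) pairs, one per requested length."""
        self._check_fitted()
        rng = (
            random_state
            if isinstance(random_state, np.random.Generator)
            else np.random.default_rng(random_state)
        )
        cum_start = np.cumsum(self.startprob_)
        cum_trans = np.cumsum(self.transmat_, axis=1)
        cum_emis = np.cumsum(self.emissionprob_, axis=1)
        out = []
        for length in lengths:
            if length < 1:
                raise ValueError("sequence lengths must be >= 1")
            last = self.n_states - 1
            u = rng.random(length)
            states = np.empty(length, dtype=np.int64)
            states[0] = min(np.searchsorted(cum_start, u[0], side="right"), last)
            for t in range(1, length):
                states[t] = min(
                    np.searchsorted(cum_trans[states[t - 1]], u[t], side="right"), last
                )
            emissions = np.minimum(
                (rng.random(length)[:, None] > cum_emis[states]).sum(axis=1),
                self.n_symbols - 1,
            ).astype(np.int64)
            out.append((states, emissions))
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "transmat_"):
            raise AttributeError(
                "model parameters not set; call fit() or set_model_params() first"
            )

    def set_model_params(self, startprob, transmat, emissionprob):
        """Install externally supplied probabilities (validated) without fitting."""
        startprob = np.asarray(startprob, dtype=np.float64)
        transmat = np.asarray(transmat, dtype=np.float64)
        emissionprob = np.asarray(emissionprob, dtype=np.float64)
        _validate_stochastic(startprob, transmat, emissionprob)
        self.startprob_ = startprob
        self.transmat_ = transmat
        self.emissionprob_ = emissionprob
        return self


def _validate_stochastic(pi: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
    if pi.ndim != 1 or a.shape != (len(pi), len(pi)) or b.shape[0] != len(pi):
        raise ValueError("inconsistent parameter shapes")
    if np.any(pi <= 0) or np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("all probabilities must be strictly positive")
    if abs(pi.sum() - 1) > _ROW_SUM_TOL:
        raise ValueError("start probabilities do not sum to 1")
    for mat, name in ((a, "transition"), (b, "emission")):
        if np.any(np.abs(mat.sum(axis=1) - 1) > _ROW_SUM_TOL):
            raise ValueError(f"{name} rows do not sum to 1")


@dataclass(frozen=True)
class HMMParams:
    """Trained model parameters plus provenance metadata.

    ``startprob`` (pi), ``transmat`` (A, rows = from-state) and
    ``emissionprob`` (B, rows = state, columns = symbol) are strictly
    positive and row-stochastic. ``metadata`` records at least the bin
    size, emission threshold and training-species list.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "startprob", np.asarray(self.startprob, np.float64))
        object.__setattr__(self, "transmat", np.asarray(self.transmat, np.float64))
        object.__setattr__(
            self, "emissionprob", np.asarray(self.emissionprob, np.float64)
        )
        _validate_stochastic(self.startprob, self.transmat, self.emissionprob)

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    def to_estimator(self) -> SupervisedCategoricalHMM:
        est = SupervisedCategoricalHMM(
            n_states=self.n_states, n_symbols=self.emissionprob.shape[1]
        )
        return est.set_model_params(self.startprob, self.transmat, self.emissionprob)

    @classmethod
    def from_estimator(
        cls, est: SupervisedCategoricalHMM, metadata: dict | None = None
    ) -> "HMMParams":
        return cls(
            startprob=est.startprob_.copy(),
            transmat=est.transmat_.copy(),
            emissionprob=est.emissionprob_.copy(),
            metadata=dict(metadata or {}),
        )


@dataclass(frozen=True)
class LabeledTrack:
    """Aligned hidden states and emission symbols for one species' grid."""

    grid: BinGrid
    states: np.ndarray
    emissions: np.ndarray
    species_id: str = ""

    def __post_init__(self) -> None:
        if len(self.states) != len(self.emissions):
            raise ValueError(
                f"states ({len(self.states)}) and emissions ({len(self.emissions)}) "
                "differ in length"
            )
        if len(self.states) != self.grid.n_bins:
            raise ValueError("track length does not match bin count")


def _track_arrays(track: LabeledTrack) -> tuple[np.ndarray, np.ndarray, list[int]]:
    return (
        np.asarray(track.emissions, np.int64),
        np.asarray(track.states, np.int64),
        track.grid.segment_lengths(),
    )


def fit_supervised(
    tracks: Sequence[LabeledTrack],
    pseudocount_transition: float = 0.001,
    pseudocount_emission: float = 1.0,
    pseudocount_start: float = 1.0,
    metadata: dict | None = None,
) -> HMMParams:
    """Supervised MLE over one or more labelled species tracks.

    Each contig of each track is one independent observation sequence:
    transitions never cross contig boundaries, and every contig contributes
    a single start-state observation.
    """
    if not tracks:
        raise ValueError("at least one labelled track is required")
    xs, ys, lengths = [], [], []
    for track in tracks:
        x, y, segs = _track_arrays(track)
        xs.append(x)
        ys.append(y)
        lengths.extend(segs)
    est = SupervisedCategoricalHMM(
        pseudocount_transition=pseudocount_transition,
        pseudocount_emission=pseudocount_emission,
        pseudocount_start=pseudocount_start,
    ).fit(np.concatenate(xs), np.concatenate(ys), lengths=lengths)
    meta = dict(metadata or {})
    meta.setdefault("species", [t.species_id for t in tracks if t.species_id])
    return HMMParams.from_estimator(est, meta)


def average_models(models: Sequence[HMMParams]) -> HMMParams:
    """Element-wise arithmetic mean of per-species models.

    All models must agree on the ``bin_size`` and ``threshold`` recorded in
    their metadata. Means of row-stochastic rows are row-stochastic up to
    floating error; rows are renormalised to enforce the invariant exactly.
    """
    if not models:
        raise ValueError("at least one model is required")
    for key in ("bin_size", "threshold"):
        values = {m.metadata.get(key) for m in models}
        if len(values) > 1:
            raise ValueError(f"models disagree on metadata {key!r}: {sorted(map(str, values))}")
    pi = np.mean([m.startprob for m in models], axis=0)
    a = np.mean([m.transmat for m in models], axis=0)
    b = np.mean([m.emissionprob for m in models], axis=0)
    pi /= pi.sum()
    a /= a.sum(axis=1, keepdims=True)
    b /= b.sum(axis=1, keepdims=True)
    species: list[str] = []
    for m in models:
        for s in m.metadata.get("species", []):
            if s not in species:
                species.append(s)
    meta = dict(models[0].metadata)
    meta["species"] = species
    meta["n_models_averaged"] = len(models)
    return HMMParams(startprob=pi, transmat=a, emissionprob=b, metadata=meta)


def viterbi_decode(params: HMMParams, emissions: EmissionTrack) -> StateTrack:
    """Decode the most likely joint state path, per contig independently."""
    est = params.to_estimator()
    states = est.predict(emissions.symbols, lengths=emissions.grid.segment_lengths())
    return StateTrack(grid=emissions.grid, states=states, provenance="predicted")


def posterior_marginals(params: HMMParams, emissions: EmissionTrack) -> np.ndarray:
    """Per-bin posterior state probabilities (n_bins x n_states), diagnostics."""
    est = params.to_estimator()
    return est.predict_proba(emissions.symbols, lengths=emissions.grid.segment_lengths())


def sample_path(
    params: HMMParams, lengths: Sequence[int], seed: int | np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample (states, emissions) sequences from the model, reproducibly."""
    return params.to_estimator().sample(lengths, random_state=seed)


# -- serialisation ----------------------------------------------------


def save_params(params: HMMParams, path: str | Path) -> None:
    """Write parameters as a small JSON document."""
    doc = {
        "startprob": params.startprob.tolist(),
        "transmat": params.transmat.tolist(),
        "emissionprob": params.emissionprob.tolist(),
        "metadata": params.metadata,
        "state_names": list(STATE_NAMES),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_params(path: str | Path) -> HMMParams:
    """Load a parameter JSON written by :func:`save_params` (or externally)."""
    with open(path) as fh:
        doc = json.load(fh)
    return HMMParams(
        startprob=np.array(doc["startprob"]),
        transmat=np.array(doc["transmat"]),
        emissionprob=np.array(doc["emissionprob"]),
        metadata=doc.get("metadata", {}),
    )


def load_pretrained(bin_size: int, threshold: float) -> HMMParams:
    """Load a bundled parameter file for a (bin_size, threshold) setting.

    The bundled files are trained on the package's synthetic corpus (their
    filenames carry ``synthetic``); they demonstrate the workflow and seed
    quick predictions, but models trained on curated real annotations
    should be preferred for production use.
    """
    name = f"synthetic_bin{int(bin_size)}_thr{threshold:g}.json"
    ref = resources.files("flamscan.data").joinpath(name)
    if not ref.is_file():
        available = sorted(
            p.name for p in resources.files("flamscan.data").iterdir()
            if p.name.endswith(".json")
        )
        raise FileNotFoundError(
            f"no bundled parameters for bin_size={bin_size}, threshold={threshold}; "
            f"available: {available}"
        )
    with resources.as_file(ref) as path:
        return load_params(path)
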