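"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle restates a definition directly (per-base masks, exhaustive
path enumeration, naive counting) and never calls the implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def nx_oracle(lengths: list[int], x: float) -> int:
    """NX by testing every distinct contig length against the definition:
    the largest length L such that contigs of length >= L cover >= x%."""
    total = sum(lengths)
    target = x * total / 100.0 - 1e-6
    candidates = [
        L for L in sorted(set(lengths), reverse=True)
        if sum(l for l in lengths if l >= L) >= target
    ]
    return max(candidates)


def coverage_oracle(
    contig_length: int,
    bin_size: int,
    features: list[tuple[int, int, str]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin covered fraction from a literal per-base boolean mask."""
    masks = {
        "+": np.zeros(contig_length, dtype=bool),
        "-": np.zeros(contig_length, dtype=bool),
    }
    for start, end, strand in features:
        masks[strand][start : min(end, contig_length)] = True
    n_bins = -(-contig_length // bin_size)
    out = []
    for strand in "+-":
        fracs = np.empty(n_bins)
        for b in range(n_bins):
            lo, hi = b * bin_size, min((b + 1) * bin_size, contig_length)
            fracs[b] = masks[strand][lo:hi].mean()
        out.append(fracs)
    return out[0], out[1]


def viterbi_oracle(
    startprob: np.ndarray,
    transmat: np.ndarray,
    emissionprob: np.ndarray,
    symbols: np.ndarray,
) -> tuple[tuple[int, ...], float]:
    """Best path and its log-probability by enumerating all state paths."""
    n = len(symbols)
    n_states = len(startprob)
    best_path, best_lp = None, -np.inf
    for path in itertools.product(range(n_states), repeat=n):
        lp = np.log(startprob[path[0]]) + np.log(emissionprob[path[0], symbols[0]])
        for t in range(1, n):
            lp += np.log(transmat[path[t - 1], path[t]])
            lp += np.log(emissionprob[path[t], symbols[t]])
        if lp > best_lp:
            best_path, best_lp = path, lp
    return best_path, best_lp


def path_logprob(
    startprob: np.ndarray,
    transmat: np.ndarray,
    emissionprob: np.ndarray,
    symbols: np.ndarray,
    path: np.ndarray,
) -> float:
    lp = np.log(startprob[path[0]]) + np.log(emissionprob[path[0], symbols[0]])
    for t in range(1, len(symbols)):
        lp += np.log(transmat[path[t - 1], path[t]])
        lp += np.log(emissionprob[path[t], symbols[t]])
    return float(lp)


def mle_oracle(
    sequences: list[tuple[np.ndarray, np.ndarray]],
    pc_trans: float = 0.001,
    pc_emis: float = 1.0,
    pc_start: float = 1.0,
    n_states: int = 3,
    n_symbols: int = 3,
):
    """Pseudocounted count-and-normalise MLE via plain Python loops."""
    start = np.full(n_states, pc_start)
    trans = np.full((n_states, n_states), pc_trans)
    emis = np.full((n_states, n_symbols), pc_emis)
    for states, emissions in sequences:
        start[states[0]] += 1
        for a, b in zip(states[:-1], states[1:]):
            trans[a, b] += 1
        for s, e in zip(states, emissions):
            emis[s, e] += 1
    return (
        start / start.sum(),
        trans / trans.sum(axis=1, keepdims=True),
        emis / emis.sum(axis=1, keepdims=True),
    )


def random_hmm_params(rng: np.random.Generator, n_states: int = 3, n_symbols: int = 3):
    """Strictly positive, row-stochastic random parameters."""
    pi = rng.random(n_states) + 0.05
    a = rng.random((n_states, n_states)) + 0.05
    b = rng.random((n_states, n_symbols)) + 0.05
    return pi / pi.sum(), a / a.sum(1, keepdims=True), b / b.sum(1, keepdims=True)
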