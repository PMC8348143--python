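"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: state paths
and posteriors come from exhaustive enumeration over all 3^T paths, interval
metrics from per-nucleotide bit vectors, and NB M-step optima from a generic
1-D bounded optimizer on the weighted log-likelihood.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from broadcall import CoverageMatrix, make_windows
from broadcall.nb import weighted_nb_loglik


@pytest.fixture
def rng():
    return np.random.default_rng(20210729)


def make_cov(values, width=800, mode="mean", chrom="chrT",
             normalized=None) -> CoverageMatrix:
    """Wrap a value array into a single-chromosome CoverageMatrix.

    Signed values (e.g. Gaussian HMM samples emulating log2-ratio tracks)
    are marked as normalized, which is the only mode that admits them.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    if normalized is None:
        normalized = mode == "mean" and bool((values < 0).any())
    windows = make_windows({chrom: values.shape[0] * width}, width)
    return CoverageMatrix(windows=windows, values=values, mode=mode,
                          normalized=normalized)


def random_hmm_params(rng, n_states=3):
    """Random start/transition simplexes."""
    start = rng.dirichlet(np.ones(n_states))
    trans = rng.dirichlet(np.ones(n_states), size=n_states)
    return start, trans


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle for paths and posteriors


def enumerate_paths(startprob, transmat, framelogprob):
    """Joint log-probability of every state path (brute force).

    Returns (paths, logprobs) over all n_states^T paths.
    """
    T, n = framelogprob.shape
    paths = list(itertools.product(range(n), repeat=T))
    logprobs = np.empty(len(paths))
    ls, lt = np.log(startprob), np.log(transmat)
    for k, path in enumerate(paths):
        lp = ls[path[0]] + framelogprob[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + framelogprob[t, path[t]]
        logprobs[k] = lp
    return paths, logprobs


def brute_force_viterbi(startprob, transmat, framelogprob):
    paths, logprobs = enumerate_paths(startprob, transmat, framelogprob)
    return np.array(paths[int(np.argmax(logprobs))])


def brute_force_posteriors(startprob, transmat, framelogprob):
    paths, logprobs = enumerate_paths(startprob, transmat, framelogprob)
    probs = np.exp(logprobs - logprobs.max())
    probs /= probs.sum()
    T, n = framelogprob.shape
    post = np.zeros((T, n))
    for path, pr in zip(paths, probs):
        for t, j in enumerate(path):
            post[t, j] += pr
    return post


# ---------------------------------------------------------------------------
# bit-vector oracle for nucleotide interval metrics


def bitvector_metrics(real, called, genome_size, chroms=("chrS",)):
    """Jaccard/TPR/FDR computed on dense per-base boolean masks."""
    inter = union = real_bp = called_bp = fp = 0
    for chrom in chroms:
        a = np.zeros(genome_size, dtype=bool)
        b = np.zeros(genome_size, dtype=bool)
        for c, s, e in real:
            if c == chrom:
                a[s:e] = True
        for c, s, e in called:
            if c == chrom:
                b[s:e] = True
        inter += int((a & b).sum())
        union += int((a | b).sum())
        real_bp += int(a.sum())
        called_bp += int(b.sum())
        fp += int((b & ~a).sum())
    return {
        "jaccard": inter / union if union else 0.0,
        "tpr": inter / real_bp if real_bp else None,
        "fdr": fp / called_bp if called_bp else None,
    }


def random_intervals(rng, genome_size, n, max_len, chrom="chrS"):
    starts = rng.integers(0, genome_size - 1, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return [(chrom, int(s), int(min(s + l, genome_size)))
            for s, l in zip(starts, lengths)]


# ---------------------------------------------------------------------------
# 1-D brute-force maximizers of the weighted NB log-likelihood


def brute_force_p(weights, x, r):
    res = minimize_scalar(
        lambda p: -weighted_nb_loglik(weights, x, r, p),
        bounds=(1e-9, 1 - 1e-9), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def brute_force_r(weights, x, p, r_max=200.0):
    res = minimize_scalar(
        lambda r: -weighted_nb_loglik(weights, x, r, p),
        bounds=(1e-6, r_max), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# simulated HMM observation sequences with known parameters


def sample_gaussian_hmm(rng, T, means=(0.0, 2.0, 10.0), sigmas=(0.5, 0.5, 0.5),
                        self_prob=0.95):
    n = len(means)
    trans = np.full((n, n), (1 - self_prob) / (n - 1))
    np.fill_diagonal(trans, self_prob)
    states = np.empty(T, dtype=int)
    states[0] = rng.integers(n)
    for t in range(1, T):
        states[t] = rng.choice(n, p=trans[states[t - 1]])
    obs = rng.normal(np.asarray(means)[states], np.asarray(sigmas)[states])
    return obs, states


def sample_nb_hmm(rng, T, rs=(1.0, 5.0, 20.0), ps=(0.5, 0.5, 0.5),
                  self_prob=0.95):
    n = len(rs)
    trans = np.full((n, n), (1 - self_prob) / (n - 1))
    np.fill_diagonal(trans, self_prob)
    states = np.empty(T, dtype=int)
    states[0] = rng.integers(n)
    for t in range(1, T):
        states[t] = rng.choice(n, p=trans[states[t - 1]])
    obs = rng.negative_binomial(np.asarray(rs)[states], np.asarray(ps)[states])
    return obs.astype(float), states
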