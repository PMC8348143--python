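"""Negative-binomial emission model and its EM M-step.

The NB distribution with parameters (r, p) — pmf C(x+r-1, x) p^r (1-p)^x,
mean r(1-p)/p — models window read counts whose variance exceeds the mean.
Inside Baum-Welch the two parameters are updated in alternation: r on even
EM iterations (via a derivative-following line search using the digamma
function), p on odd iterations (closed-form weighted MLE). Each update is a
coordinate-ascent step on the EM Q-function, so the data log-likelihood is
non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .errors import StateCollapseError

log = logging.getLogger(__name__)

P_EPS = 1e-10
R_SEARCH_THRESHOLD = 1e-5
R_SEARCH_MAX_INNER = 100
_ZERO_WEIGHT = 1e-12


def nb_logpmf(x: np.ndarray, r: float, p: float) -> np.ndarray:
    """Log pmf of NB(r, p) at non-negative integer counts x."""
    x = np.asarray(x, dtype=float)
    return (
        gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
        + r * np.log(p) + x * np.log1p(-p)
    )


def weighted_nb_loglik(weights: np.ndarray, x: np.ndarray, r: float, p: float) -> float:
    """Posterior-weighted NB log-likelihood (the per-state EM objective)."""
    return float(np.dot(weights, nb_logpmf(x, r, p)))


def nb_p_mstep(posteriors_j: np.ndarray, x: np.ndarray, r_j: float) -> float:
    """Closed-form weighted MLE of p for one state, r held fixed.

    p_j = sum_t P_jt * r_j / sum_t P_jt * (x_t + r_j), clamped into (0, 1).
    """
    w = np.asarray(posteriors_j, dtype=float)
    wsum = w.sum()
    if wsum <= _ZERO_WEIGHT:
        raise StateCollapseError("state has zero posterior weight; cannot update p")
    num = wsum * r_j
    den = float(np.dot(w, np.asarray(x, dtype=float) + r_j))
    return float(np.clip(num / den, P_EPS, 1.0 - P_EPS))


def nb_dldr(posteriors_j: np.ndarray, x: np.ndarray, p_j: float, r: float) -> float:
    """Derivative of the weighted NB log-likelihood with respect to r.

    dl/dr = sum_t P_jt * [psi(x_t + r) - psi(r) + ln(p_j)] where psi is the
    digamma function.
    """
    w = np.asarray(posteriors_j, dtype=float)
    x = np.asarray(x, dtype=float)
    return float(np.dot(w, digamma(x + r) - digamma(r) + np.log(p_j)))


@dataclass
class RSearchState:
    """Trace of the iterative r search (diagnostic)."""

    r_current: float
    delta: float = 0.0
    derivative: float = 0.0
    iteration: int = 0


def nb_r_mstep(
    posteriors_j: np.ndarray,
    x: np.ndarray,
    p_j: float,
    r_start: float,
    threshold: float = R_SEARCH_THRESHOLD,
    max_inner: int = R_SEARCH_MAX_INNER,
) -> float:
    """Derivative-following search for the weighted MLE of r, p held fixed.

    Starting from the previous estimate r_0, the step Delta follows the sign
    of dl/dr: while the derivative keeps its sign the step is kept, on a sign
    change the step is halved and reversed, and the very first step is +r_0
    (uphill) or -r_0/2 (downhill). Iteration stops once |dl/dr| falls below
    ``threshold``. A positivity guard halves any step that would push r to or
    below zero; if ``max_inner`` is reached the best r seen (by weighted
    log-likelihood) is returned with a warning.
    """
    if r_start <= 0:
        raise ValueError(f"r_start must be positive, got {r_start}")
    w = np.asarray(posteriors_j, dtype=float)
    if w.sum() <= _ZERO_WEIGHT:
        raise StateCollapseError("state has zero posterior weight; cannot update r")

    state = RSearchState(r_current=float(r_start))
    r0 = float(r_start)
    best_r = state.r_current
    best_ll = weighted_nb_loglik(w, x, state.r_current, p_j)
    for state.iteration in range(max_inner):
        state.derivative = nb_dldr(w, x, p_j, state.r_current)
        if abs(state.derivative) < threshold:
            return state.r_current
        if state.derivative > 0:
            if state.delta > 0:
                pass  # keep climbing with the same step
            elif state.delta < 0:
                state.delta = -0.5 * state.delta
            else:
                state.delta = r0
        else:
            if state.delta > 0:
                state.delta = -0.5 * state.delta
            elif state.delta < 0:
                pass
            else:
                state.delta = -0.5 * r0
        while state.r_current + state.delta <= 0:
            state.delta *= 0.5
            log.debug("halved r step to %.3g to keep r positive", state.delta)
        state.r_current += state.delta
        ll = weighted_nb_loglik(w, x, state.r_current, p_j)
        if ll > best_ll:
            best_ll, best_r = ll, state.r_current
    log.warning(
        "r search hit the iteration cap (%d); returning best r seen (%.4g)",
        max_inner, best_r,
    )
    return best_r


@dataclass
class NBEmission:
    """Per-state (x per-dimension) negative-binomial emission parameters.

    For D > 1 the dimensions are modelled as independent NB variables per
    state (product likelihood).
    """

    p: np.ndarray  # (3, D), success probabilities in (0, 1)
    r: np.ndarray  # (3, D), dispersions > 0

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        if self.p.shape != self.r.shape:
            raise ValueError("p and r must have the same shape")
        if not ((self.p > 0) & (self.p < 1)).all():
            raise ValueError("p must lie strictly in (0, 1)")
        if not (self.r > 0).all():
            raise ValueError("r must be positive")

    @property
    def n_states(self) -> int:
        return self.p.shape[0]

    @property
    def n_features(self) -> int:
        return self.p.shape[1]

    def means(self) -> np.ndarray:
        """Implied per-state, per-dimension means r(1-p)/p."""
        return self.r * (1.0 - self.p) / self.p

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """(T, n_states) log emission probabilities for integer counts x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.ndim == 2 and x.shape[1] != self.n_features:
            x = x.reshape(-1, self.n_features)
        out = np.zeros((x.shape[0], self.n_states))
        for j in range(self.n_states):
            for d in range(self.n_features):
                out[:, j] += nb_logpmf(x[:, d], float(self.r[j, d]), float(self.p[j, d]))
        return out


def nb_m_step(posteriors: np.ndarray, x: np.ndarray, emissions: NBEmission,
              em_iteration: int) -> NBEmission:
    """One alternating NB M-step: r on even EM iterations, p on odd ones.

    States (and dimensions) with zero posterior weight keep their previous
    parameters for this iteration.
    """
    if em_iteration < 0:
        raise ValueError("em_iteration must be >= 0")
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    if x2.shape[0] != posteriors.shape[0]:
        x2 = x2.reshape(posteriors.shape[0], -1)
    new_p = emissions.p.copy()
    new_r = emissions.r.copy()
    for j in range(emissions.n_states):
        w = posteriors[:, j]
        if w.sum() <= _ZERO_WEIGHT:
            log.debug("state %d has zero weight; NB parameters frozen", j)
            continue
        for d in range(emissions.n_features):
            if em_iteration % 2 == 0:
                new_r[j, d] = nb_r_mstep(w, x2[:, d], float(emissions.p[j, d]),
                                         float(emissions.r[j, d]))
            else:
                new_p[j, d] = nb_p_mstep(w, x2[:, d], float(emissions.r[j, d]))
    return NBEmission(p=new_p, r=new_r)
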