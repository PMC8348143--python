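"""Three-state hidden Markov model over genome windows.

States are "no signal", "background" and "peak"; emissions are per-window
coverage values, modelled as Gaussian (mean coverage, optionally control
normalized) or negative binomial (summed counts). Training is Baum-Welch
(EM); decoding is Viterbi for the state path and forward-backward for
per-window posteriors. All recursions run in log space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .coverage import CoverageMatrix
from .errors import (ConfigurationError, DegenerateDataError, DimensionError,
                     NumericalError)
from .nb import NBEmission, nb_m_step

log = logging.getLogger(__name__)

N_STATES = 3
STATE_ROLES = ("no_signal", "background", "peak")
INIT_QUANTILES = (0.0, 0.5, 0.99)
VARIANCE_FLOOR = 1e-6
COVARIANCE_TYPES = ("diagonal", "full", "spherical", "tied")
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 100


@dataclass
class GaussianEmission:
    """Per-state Gaussian emission parameters.

    ``covariance_type`` controls the parameterization: "diagonal" stores a
    (3, D) array of per-dimension variances, "spherical" a single variance
    per state, "full" a (3, D, D) stack and "tied" one (D, D) matrix shared
    by all states. Variances are floored at a small epsilon to prevent state
    collapse onto a single data point.
    """

    means: np.ndarray  # (3, D)
    covars: np.ndarray
    covariance_type: str = "diagonal"

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covars = np.asarray(self.covars, dtype=float)
        if self.covariance_type not in COVARIANCE_TYPES:
            raise ConfigurationError(
                f"covariance_type must be one of {COVARIANCE_TYPES}"
            )

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def state_cov(self, j: int) -> np.ndarray:
        """Full (D, D) covariance matrix of state j."""
        d = self.n_features
        if self.covariance_type == "diagonal":
            return np.diag(self.covars[j])
        if self.covariance_type == "spherical":
            return float(self.covars[j]) * np.eye(d)
        if self.covariance_type == "tied":
            return self.covars
        return self.covars[j]

    def means_summary(self) -> np.ndarray:
        """Per-state scalar summary (sum over dimensions) used for ranking."""
        return self.means.sum(axis=1)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], self.n_states))
        for j in range(self.n_states):
            out[:, j] = multivariate_normal.logpdf(
                x, mean=self.means[j], cov=self.state_cov(j), allow_singular=True
            )
        return out


@dataclass
class PeakHMM:
    """Start probabilities, transition matrix and an emission model."""

    startprob: np.ndarray  # (3,) simplex
    transmat: np.ndarray  # (3, 3) row-stochastic
    emissions: GaussianEmission | NBEmission
    state_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        if self.startprob.shape != (N_STATES,) or self.transmat.shape != (N_STATES, N_STATES):
            raise DimensionError("model must have exactly three states")
        if abs(self.startprob.sum() - 1.0) > 1e-9:
            raise ConfigurationError("start probabilities must sum to 1")
        if np.abs(self.transmat.sum(axis=1) - 1.0).max() > 1e-9:
            raise ConfigurationError("transition rows must sum to 1")

    @property
    def distribution(self) -> str:
        return "nb" if isinstance(self.emissions, NBEmission) else "gaussian"

    @property
    def n_features(self) -> int:
        return self.emissions.n_features

    def emission_means(self) -> np.ndarray:
        """Per-state scalar emission means (summed over dimensions)."""
        if isinstance(self.emissions, NBEmission):
            return self.emissions.means().sum(axis=1)
        return self.emissions.means_summary()


# ---------------------------------------------------------------------------
# log-space recursions


def _check_finite_frames(framelogprob: np.ndarray) -> None:
    bad = ~np.isfinite(framelogprob.max(axis=1))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise NumericalError(
            f"emission log-probability is non-finite in every state at window {idx}"
        )


def forward_backward(startprob: np.ndarray, transmat: np.ndarray,
                     framelogprob: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward for one sequence.

    Emission probabilities are shifted per window before exponentiation and
    the forward variables renormalized at every step, so the recursion never
    under- or overflows; the log-likelihood is recovered from the running
    scale factors. Returns (gamma, xi_sum, loglik) where gamma is (T, 3)
    state posteriors and xi_sum the (3, 3) expected transition counts.
    """
    T = framelogprob.shape[0]
    shift = framelogprob.max(axis=1)
    b = np.exp(framelogprob - shift[:, None])  # row max == 1

    alpha = np.empty((T, N_STATES))
    scale = np.empty(T)
    alpha[0] = startprob * b[0]
    scale[0] = alpha[0].sum()
    if scale[0] <= 0:
        raise NumericalError("forward pass underflowed at window 0")
    alpha[0] /= scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transmat) * b[t]
        s = a.sum()
        if s <= 0:
            raise NumericalError(f"forward pass underflowed at window {t}")
        alpha[t] = a / s
        scale[t] = s
    loglik = float(np.log(scale).sum() + shift.sum())

    beta = np.empty((T, N_STATES))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = transmat @ (b[t + 1] * beta[t + 1]) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.einsum("ti,tj->ij", alpha[:-1],
                       b[1:] * beta[1:] / scale[1:, None]) * transmat
    return gamma, xi_sum, loglik


def viterbi_log(log_start: np.ndarray, log_trans: np.ndarray,
                framelogprob: np.ndarray) -> np.ndarray:
    T = framelogprob.shape[0]
    score = log_start + framelogprob[0]
    back = np.empty((T, N_STATES), dtype=np.int64)
    for t in range(1, T):
        cand = score[:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        score = cand.max(axis=0) + framelogprob[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(score.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# initialization


def init_model(data: CoverageMatrix, distribution: str = "gaussian",
               user_means: np.ndarray | None = None,
               covariance_type: str = "diagonal") -> PeakHMM:
    """Initialize the three-state model from the data.

    State emission means start at the 0, 0.5 and 0.99 quantiles of the
    coverage values (linear interpolation), so the lowest state tracks empty
    windows, the middle one background and the top one enrichment. Gaussian
    covariances start at the sample covariance; NB parameters come from the
    moment relations p = mean/var and r = mean^2/(var - mean). Start and
    transition probabilities are uniform.
    """
    x = data.values
    if x.size == 0:
        raise DegenerateDataError("empty coverage matrix")
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            "coverage is constant across all windows; the three-state model "
            "cannot be fit — check the input files and window width"
        )
    d = x.shape[1]
    if user_means is not None:
        means = np.asarray(user_means, dtype=float)
        if means.shape != (N_STATES, d):
            raise ConfigurationError(
                f"user means must have shape {(N_STATES, d)}, got {means.shape}"
            )
    else:
        means = np.quantile(x, INIT_QUANTILES, axis=0)
        if x.shape[0] < 100:
            log.debug("0.99 quantile estimated from only %d windows", x.shape[0])

    startprob = np.full(N_STATES, 1.0 / N_STATES)
    transmat = np.full((N_STATES, N_STATES), 1.0 / N_STATES)

    if distribution == "gaussian":
        var = np.maximum(x.var(axis=0), VARIANCE_FLOOR)  # (D,)
        if covariance_type == "diagonal":
            covars = np.tile(var, (N_STATES, 1))
        elif covariance_type == "spherical":
            covars = np.full(N_STATES, float(var.mean()))
        else:
            cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=0))
            cov[np.diag_indices_from(cov)] = np.maximum(np.diag(cov), VARIANCE_FLOOR)
            covars = cov if covariance_type == "tied" else np.tile(cov, (N_STATES, 1, 1))
        emissions = GaussianEmission(means=means, covars=covars,
                                     covariance_type=covariance_type)
    elif distribution == "nb":
        if data.mode != "sum" or data.normalized:
            raise ConfigurationError(
                "negative-binomial emissions require summed, unnormalized "
                "integer counts (mode='sum')"
            )
        var = x.var(axis=0)  # (D,)
        m = np.maximum(means, 1e-2)  # quantile-0 target is usually 0
        v = np.broadcast_to(var, m.shape).copy()
        floored = v <= m
        if floored.any():
            log.info(
                "sample variance <= target mean for %d state/dimension pairs; "
                "floored to mean*1.001 for NB moment initialization",
                int(floored.sum()),
            )
            v[floored] = m[floored] * 1.001
        p = np.clip(m / v, 1e-10, 1 - 1e-10)
        r = m ** 2 / (v - m)
        emissions = NBEmission(p=p, r=r)
    else:
        raise ConfigurationError(f"unknown distribution {distribution!r}")
    return PeakHMM(startprob=startprob, transmat=transmat, emissions=emissions)


# ---------------------------------------------------------------------------
# training


def _sequences(data: CoverageMatrix) -> list[slice]:
    """Each chromosome is an independent observation sequence."""
    return [data.windows.chrom_slice(c) for c in data.windows.chrom_order]


def fit_baum_welch(model: PeakHMM, data: CoverageMatrix,
                   tol: float = DEFAULT_TOL,
                   max_iter: int = DEFAULT_MAX_ITER) -> tuple[PeakHMM, list[float]]:
    """Baum-Welch (EM) training.

    Each chromosome is treated as an independent observation sequence.
    Iterates until the change in total log-likelihood drops below ``tol`` or
    ``max_iter`` is reached; returns the trained model and the per-iteration
    log-likelihood trace. With NB emissions the M-step alternates r and p
    updates across EM iterations.
    """
    x = data.values
    seqs = _sequences(data)
    trace: list[float] = []
    for it in range(max_iter):
        framelogprob = model.emissions.log_density(x)
        _check_finite_frames(framelogprob)

        total_ll = 0.0
        start_counts = np.zeros(N_STATES)
        xi_sum = np.zeros((N_STATES, N_STATES))
        gamma = np.empty((x.shape[0], N_STATES))
        for sl in seqs:
            frames = framelogprob[sl]
            if frames.shape[0] == 0:
                continue
            g, xi, ll = forward_backward(model.startprob, model.transmat, frames)
            total_ll += ll
            gamma[sl] = g
            start_counts += g[0]
            xi_sum += xi
        if not np.isfinite(total_ll):
            raise NumericalError("log-likelihood became non-finite during training")
        trace.append(total_ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break

        # M-step
        startprob = start_counts / start_counts.sum()
        rowsums = xi_sum.sum(axis=1, keepdims=True)
        transmat = np.where(rowsums > 0, xi_sum / np.maximum(rowsums, 1e-300),
                            model.transmat)
        transmat /= transmat.sum(axis=1, keepdims=True)
        if isinstance(model.emissions, NBEmission):
            emissions = nb_m_step(gamma, x, model.emissions, em_iteration=it)
        else:
            emissions = _gaussian_m_step(gamma, x, model.emissions)
        model = PeakHMM(startprob=startprob, transmat=transmat, emissions=emissions)
    return model, trace


def _gaussian_m_step(gamma: np.ndarray, x: np.ndarray,
                     emissions: GaussianEmission) -> GaussianEmission:
    d = x.shape[1]
    weights = gamma.sum(axis=0)  # (3,)
    means = emissions.means.copy()
    ctype = emissions.covariance_type
    covars = emissions.covars.copy()

    tied_acc = np.zeros((d, d))
    for j in range(N_STATES):
        if weights[j] <= 1e-12:
            log.debug("state %d has zero weight; Gaussian parameters frozen", j)
            tied_acc += weights[j] * emissions.state_cov(j)
            continue
        means[j] = gamma[:, j] @ x / weights[j]
        diff = x - means[j]
        if ctype == "diagonal":
            covars[j] = np.maximum(gamma[:, j] @ (diff ** 2) / weights[j],
                                   VARIANCE_FLOOR)
        elif ctype == "spherical":
            covars[j] = max(float((gamma[:, j] @ (diff ** 2)).sum()
                                  / (weights[j] * d)), VARIANCE_FLOOR)
        else:
            s = (gamma[:, j, None] * diff).T @ diff / weights[j]
            s[np.diag_indices_from(s)] = np.maximum(np.diag(s), VARIANCE_FLOOR)
            if ctype == "full":
                covars[j] = s
            else:  # tied
                tied_acc += weights[j] * s
    if ctype == "tied":
        covars = tied_acc / weights.sum()
        covars[np.diag_indices_from(covars)] = np.maximum(np.diag(covars),
                                                          VARIANCE_FLOOR)
    return GaussianEmission(means=means, covars=covars, covariance_type=ctype)


# ---------------------------------------------------------------------------
# decoding


def viterbi_decode(model: PeakHMM, data: CoverageMatrix) -> np.ndarray:
    """Most probable state path, decoded independently per chromosome."""
    framelogprob = model.emissions.log_density(data.values)
    _check_finite_frames(framelogprob)
    log_start = np.log(np.maximum(model.startprob, 1e-300))
    log_trans = np.log(np.maximum(model.transmat, 1e-300))
    path = np.empty(len(data.windows), dtype=np.int64)
    for sl in _sequences(data):
        if framelogprob[sl].shape[0]:
            path[sl] = viterbi_log(log_start, log_trans, framelogprob[sl])
    return path


def posterior_decode(model: PeakHMM, data: CoverageMatrix) -> np.ndarray:
    """Forward-backward state posteriors, (T, 3), rows summing to 1."""
    framelogprob = model.emissions.log_density(data.values)
    _check_finite_frames(framelogprob)
    post = np.empty((len(data.windows), N_STATES))
    for sl in _sequences(data):
        frames = framelogprob[sl]
        if not frames.shape[0]:
            continue
        post[sl], _, _ = forward_backward(model.startprob, model.transmat, frames)
    return post


def label_states(model: PeakHMM) -> tuple[str, ...]:
    """Assign roles by emission mean: lowest = no_signal, highest = peak.

    For multivariate emissions the per-dimension means are summed before
    ranking; ties keep the original state order (stable sort).
    """
    means = model.emission_means()
    order = np.argsort(means, kind="stable")
    if len(np.unique(means)) < N_STATES:
        log.warning("tied emission means %s; tie broken by state index", means)
    labels = [""] * N_STATES
    for role, j in zip(STATE_ROLES, order):
        labels[int(j)] = role
    return tuple(labels)


def peak_state(model: PeakHMM) -> int:
    """Index of the state labelled 'peak'."""
    labels = model.state_labels or label_states(model)
    return labels.index("peak")


# ---------------------------------------------------------------------------
# persistence


def save_model(model: PeakHMM, path: str) -> None:
    """Dump the model as a plain-text key: value file (JSON-encoded arrays)."""
    payload: dict[str, object] = {
        "distribution": model.distribution,
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "state_labels": list(model.state_labels or label_states(model)),
    }
    if isinstance(model.emissions, NBEmission):
        payload["p"] = model.emissions.p.tolist()
        payload["r"] = model.emissions.r.tolist()
    else:
        payload["means"] = model.emissions.means.tolist()
        payload["covars"] = model.emissions.covars.tolist()
        payload["covariance_type"] = model.emissions.covariance_type
    with open(path, "w") as fh:
        for key, value in payload.items():
            fh.write(f"{key}: {json.dumps(value)}\n")


def load_model(path: str) -> PeakHMM:
    payload: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, value = line.partition(":")
            payload[key.strip()] = json.loads(value)
    if payload["distribution"] == "nb":
        emissions: GaussianEmission | NBEmission = NBEmission(
            p=np.array(payload["p"]), r=np.array(payload["r"])
        )
    else:
        emissions = GaussianEmission(
            means=np.array(payload["means"]),
            covars=np.array(payload["covars"]),
            covariance_type=str(payload["covariance_type"]),
        )
    return PeakHMM(
        startprob=np.array(payload["startprob"]),
        transmat=np.array(payload["transmat"]),
        emissions=emissions,
        state_labels=tuple(payload["state_labels"]),
    )
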