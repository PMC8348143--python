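"""End-to-end peak calling: windows -> coverage -> HMM -> scored peaks."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import coverage as cov
from . import hmm, peaks
from .errors import ConfigurationError
from .windows import DEFAULT_WINDOW_WIDTH, GenomeWindows, make_windows, read_chrom_sizes

log = logging.getLogger(__name__)


@dataclass
class CallResult:
    peaks: peaks.PeakSet
    model: hmm.PeakHMM
    loglik_trace: list[float]
    states: np.ndarray  # per-window state indices
    labels: np.ndarray  # per-window role strings
    posteriors: np.ndarray  # (T, 3)
    coverage: cov.CoverageMatrix
    windows: GenomeWindows


def call_peaks(
    chip_paths: list[str],
    chrom_sizes: dict[str, int] | str,
    control_path: str | None = None,
    width: int = DEFAULT_WINDOW_WIDTH,
    distribution: str = "gaussian",
    covariance_type: str = "diagonal",
    merge: str = "sum",
    tol: float = hmm.DEFAULT_TOL,
    max_iter: int = hmm.DEFAULT_MAX_ITER,
    user_means: np.ndarray | None = None,
    seed: int = 0,
) -> CallResult:
    """Run the whole peak-calling workflow on alignment/coverage files.

    Gaussian emissions consume per-window mean coverage (optionally log2
    control-normalized), negative-binomial emissions consume summed counts.
    With several ChIP samples, ``merge`` picks between summing the signals
    and treating them as a vector-valued emission. ``seed`` pins any
    stochastic tie-breaking for reproducibility (the pipeline is otherwise
    deterministic).
    """
    if distribution not in ("gaussian", "nb"):
        raise ConfigurationError(f"unknown distribution {distribution!r}")
    if control_path is not None and distribution != "gaussian":
        raise ConfigurationError(
            "a control sample can only be used with Gaussian emissions: "
            "log2 ratios are not integer counts"
        )
    if not chip_paths:
        raise ConfigurationError("at least one ChIP sample is required")
    np.random.seed(seed % (2 ** 31))

    if isinstance(chrom_sizes, str):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    windows = make_windows(chrom_sizes, width)
    aggregator = "mean" if distribution == "gaussian" else "sum"

    columns = [cov.bin_coverage(p, windows, aggregator) for p in chip_paths]
    if control_path is not None:
        control = cov.bin_coverage(control_path, windows, "mean")
        # each ChIP column is normalized against the single control before merging
        columns = [cov.normalize_with_control(c, control) for c in columns]
    data = cov.combine_samples(columns, strategy=merge)

    model = hmm.init_model(data, distribution=distribution,
                           user_means=user_means, covariance_type=covariance_type)
    model, trace = hmm.fit_baum_welch(model, data, tol=tol, max_iter=max_iter)
    model.state_labels = hmm.label_states(model)
    log.info("EM finished after %d iterations (final log-likelihood %.4f)",
             len(trace), trace[-1] if trace else float("nan"))

    states = hmm.viterbi_decode(model, data)
    posteriors = hmm.posterior_decode(model, data)
    labels = np.array(model.state_labels, dtype=object)[states]
    peak_set = peaks.merge_peak_windows(labels, windows, peak_label="peak")
    peak_set = peaks.score_peaks(peak_set, data, posteriors,
                                 peak_state=hmm.peak_state(model))
    peak_set.provenance = {
        "chip": list(chip_paths), "control": control_path, "width": width,
        "distribution": distribution, "covariance_type": covariance_type,
        "merge": merge, "tol": tol, "max_iter": max_iter, "seed": seed,
    }
    return CallResult(
        peaks=peak_set, model=model, loglik_trace=trace, states=states,
        labels=labels, posteriors=posteriors, coverage=data, windows=windows,
    )
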