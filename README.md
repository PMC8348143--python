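# broadcall

HMM-based peak calling for **broad, weakly enriched ChIP-seq domains** —
the kind produced by repressive histone marks such as H3K27me3, which form
domains spanning tens of kilobases to megabases at enrichment levels where
conventional enrichment-test peak callers struggle. `broadcall` is for
epigenomics researchers who need to segment such signal from aligned reads
or coverage tracks, and for method developers who want a self-contained
simulator and nucleotide-level benchmark metrics alongside the caller.

## The model

The genome is tiled into adjacent fixed-width windows (800 bp by default).
The per-window signal `x_t` is modelled by a three-state hidden Markov model
with states *no signal*, *background* and *peak*:

- **Gaussian emissions** (default): `x_t` is the mean per-base coverage of
  window *t*; state *j* emits `N(μ_j, Σ_j)` with diagonal, full, spherical
  or tied covariance. With a control (input) sample the signal becomes
  `log2((chip + 1) / (control + 1))` per window.
- **Negative-binomial emissions**: `x_t` is the summed read count; state *j*
  emits `NB(r_j, p_j)` with mean `r_j (1 − p_j) / p_j`, capturing the
  overdispersion of real read counts.

Parameters are estimated by Baum–Welch (EM). State means initialize at the
0, 0.5 and 0.99 quantiles of the data. For NB emissions the M-step has no
closed form in `r`, so `r` and `p` are updated in alternation:

- `p_j = Σ_t P_{j,t} r_j / Σ_t P_{j,t}(x_t + r_j)` (closed-form weighted MLE),
- `r_j` by a derivative-following search on
  `dl/dr = Σ_t P_{j,t} [Ψ(x_t + r) − Ψ(r) + ln p_j]` (Ψ = digamma), where the
  step keeps its size while the derivative keeps its sign and halves and
  reverses on a sign change, stopping when `|dl/dr| < 1e-5`.

Here `P_{j,t}` is the forward–backward posterior that window *t* is in state
*j*. The Viterbi path assigns each window a state; maximal runs of
peak-state windows (merged across adjacency, never across chromosomes)
become peaks, each scored four ways: mean coverage, maximum coverage, the
product of per-window peak posteriors, and the maximum posterior.

Multiple ChIP samples can be summed into one track or treated as a
vector-valued emission (`--merge sum|vector`).

## Worked example

`examples/simulate_and_call.py` plants twenty 20 kb domains on a 2 Mb
chromosome with peak reads adding mean coverage 3 over a uniform background
of coverage 3 — enrichment equal to the noise level — then calls peaks with
defaults and compares against the planted truth:

```
truth peaks: 20, called: 20
TPR     = 0.9925  (fraction of truth bp recovered)
FDR     = 0.0154  (fraction of called bp outside truth)
Jaccard = 0.9774  (bp intersection / union)
strongest peak: chrS:1020000-1040000 mean coverage 6.20, max posterior 1.000
```

Despite only a twofold coverage difference (6 vs 3), persistence across the
25 windows of each domain lets the HMM recover >99% of truth nucleotides
with ~1.5% false-discovery. The other examples demonstrate the
negative-binomial fit (`negative_binomial_fit.py`) and the interval metrics
(`interval_metrics.py`).

## Command line

```bash
broadcall simulate --config cfg.txt --out sim          # dataset + truth BED
broadcall call --chip sim_coverage.bedgraph \
               --chrom-sizes sim_chrom.sizes \
               --width 800 --distribution gaussian --out run
broadcall evaluate --truth sim_truth.bed --called run_peaks.bed
```

`call` accepts BAM/SAM or bedGraph input, repeated `--chip` for replicates,
`--control` (Gaussian only), `--covariance`, `--merge`, `--score` to choose
the BED score column, `--tol`/`--max-iter` for EM, and `--seed`. It writes
`PREFIX_peaks.bed` (BED5), `PREFIX_peaks.tab` (all four scores) and
`PREFIX_model.txt` (the fitted model).

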