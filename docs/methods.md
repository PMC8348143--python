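# Methods

## Model and procedure

`broadcall` segments per-window ChIP-seq signal with a three-state hidden
Markov model. The states are interpreted post hoc by ranking emission means:
the lowest-mean state is *no signal* (empty windows), the middle one
*background* (nonspecific reads), the highest *peak* (enrichment). The model
assumes (i) signal within a state is i.i.d. given the state, (ii) state
durations are geometric — adequate for broad domains, where persistence over
many windows, not emission strength in single windows, carries the evidence,
and (iii) chromosomes are independent observation sequences.

Two emission families are supported. Gaussian emissions consume the mean
per-base coverage per window (a real value; after control normalization,
`log2((chip+1)/(control+1))`, possibly negative). Negative-binomial
emissions consume summed integer counts and capture overdispersion
(variance > mean) directly; they cannot be combined with a control because
log-ratios are not counts. For multivariate input (several samples kept as a
vector), Gaussian states use a covariance matrix (diagonal / full /
spherical / tied), and NB states model dimensions as independent NB
variables (product likelihood) — a pragmatic choice, since no standard
multivariate NB exists.

## Initialization

State means start at the 0, 0.5 and 0.99 data quantiles (linear
interpolation), which seeds the no-signal/background/peak ordering without
labels. Gaussian covariances start at the sample covariance. NB parameters
come from moment matching per state: with target mean m (the state's
quantile) and the sample variance v, `p = m/v` and `r = m²/(v − m)`. Two
guards keep this well-defined: m is floored at 0.01 (the 0-quantile is
usually 0), and v is floored at `1.001·m` when the data are underdispersed,
both logged. Start and transition probabilities initialize uniform (1/3), to
avoid prejudging segment lengths.

## Training and decoding

Baum–Welch runs until the absolute change in total log-likelihood falls
below `tol` (default 1e-3) or `max_iter` (default 100) iterations. The
forward–backward pass uses per-step renormalization on top of a per-window
log-shift of the emission densities; this is algebraically equivalent to the
log-space recursion but vectorizes far better (about 20× faster at 2,500
windows) and cannot under- or overflow — the log-likelihood is recovered
from the accumulated scale factors. Viterbi decoding runs in log space.

The Gaussian M-step is the standard weighted update with a variance floor of
1e-6 to prevent state collapse; states with zero posterior weight keep their
previous parameters for that iteration. The NB M-step alternates: `r` is
updated on even EM iterations (starting with iteration 0), `p` on odd ones.
Each alternating update maximizes the EM Q-function in one coordinate with
the other held fixed, i.e. generalized EM, so the data log-likelihood is
non-decreasing (the test suite verifies this to 1e-6 slack over 20
iterations).

The `r` search follows the sign of `dl/dr = Σ_t P_{j,t}[Ψ(x_t+r) − Ψ(r) +
ln p_j]`: the first step is `+r₀` uphill or `−r₀/2` downhill; a step that
keeps the derivative's sign is repeated, a sign change halves and reverses
it. The stop rule is `|dl/dr| < 1e-5`; the absolute value is used — with a
signed reading a negative derivative would never terminate. Two safety
measures not inherent to the scheme: an iteration cap of 100 (returning the
best `r` seen by weighted likelihood, with a warning), and halving any step
that would drive `r ≤ 0`.

## Windows, coverage and peaks

Windows are 0-based half-open, tiling each chromosome from 0 in multiples of
the width; the final window is truncated at the chromosome end and is
included (its mean uses its actual length) — dropping it would lose terminal
peaks. Reads are counted by per-base pileup of the aligned span; there is no
fragment-size extension, shifting, strand handling, duplicate removal or
mappability correction. Chromosomes missing from an input get all-zero
coverage with a warning. Fractional sum-mode values (possible from bedGraph
input) are rounded to integers with a warning, since NB emissions need
counts. With a control, each ChIP column is normalized against the single
control before multi-sample combination.

Peak scores: mean and max of window coverages (summed across samples in
vector mode), and the product and max of per-window peak-state posteriors.
The product is computed as `exp(Σ log)` and stored as 0 below ~1e-300.

## Window width

The default width is 800 bp; widths of roughly 300–1000 bp work well across
peak sizes, and ~1000 bp is usually sufficient when the target is long
domains. Shorter windows raise resolution in principle but expose the model
to much noisier per-window values and many more transitions, hurting
convergence.

## The simulator

The generator emulates the coverage structure of a broad-mark experiment on
one synthetic chromosome: truth peaks of one fixed width placed at template
start positions (a peak overlapping its predecessor, or running past the
genome end, is dropped — and, when sets of several widths are built
together, dropped from every set so counts stay comparable); background
reads uniform over the chromosome at mean fold-coverage x (`x·G/L` reads of
length L on a genome of G bp); peak reads uniform within a uniformly chosen
peak at mean fold-coverage y (`y·width·n_peaks/L` reads). Mean coverage over
peak regions is therefore x + y. Reads are position spans sampled directly
with a seeded generator — no sequences, no aligner — so mapping biases, GC
effects, paired ends and mappability holes of real data are absent: passing
benchmarks here demonstrates the statistical machinery under the stated
coverage model, not robustness to alignment artifacts. The default grid
spans peak widths 50–50,000 bp, peak coverages 2–25 and noise coverages
0.25–5 (18 × 7 × 6 configurations).

## Evaluation metrics

Jaccard, TPR and FDR count nucleotides of half-open intervals, pooled
genome-wide, after merging overlapping/adjacent intervals within each input
set. TPR is undefined (an error) for an empty truth set, FDR for an empty
called set; an empty union yields Jaccard 0. Gene overlap uses a 1 bp
threshold. All three are verified against dense per-base bit-vector oracles
and, for Jaccard, against an independent interval toolkit.

## Benchmark scale

The shipped benchmark (`scripts/acceptance.py`) uses a 2 Mb chromosome with
twenty 20 kb domains at peak coverage 3 over noise 3 with 100 bp reads —
2,500 windows of 800 bp. This scale gives stable sensitivity estimates
(±~1% across seeds) while running in seconds; the published-scale analogue
(chromosome-sized genomes, 157 peaks) changes only the amount of data, not
the procedure.

## Known limitations

- Exactly three states; no semi-Markov duration modelling, so very short
  interruptions inside a domain can split peaks.
- Geometric duration assumption biases towards exponential-ish peak length
  mixtures at a given transition matrix.
- The NB vector mode ignores inter-sample correlation.
- EM finds local optima; the quantile initialization is a good basin for
  unimodal-background data but all-constant or near-constant coverage is
  rejected rather than fit.
- No p-/q-values: peak scores are coverage- and posterior-based.
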