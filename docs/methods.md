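# Methods

This note documents the models and estimators implemented in `latentlearn`,
the conventions chosen where several were defensible, and what the
synthetic benchmarks do and do not establish.

## Task and latent graphs

Stimuli are generated by a uniform random walk on a 10-node, 4-regular
graph. Two topologies are provided. The *modular* graph splits the nodes
into two five-node modules; with degree 4 and two modules of five, the
interior nodes must connect to every other member of their module, the two
boundary nodes of each module cannot be adjacent to each other, and the
modules join through exactly two cross edges — here (4,5) and (9,0). This
is the unique minimal-cross-edge topology consistent with those
constraints; the walk's start node is uniform. The *lattice* graph
connects each node to its nearest and next-nearest neighbours on a ring
(edge iff (i−j) mod 10 ∈ {1,2,8,9}). Because both graphs are 4-regular,
every edge transition has probability 1/4 and the stationary distribution
is uniform: the graphs differ only in higher-order structure. Stimulus
identities are assigned to nodes by an explicit permutation so that visual
and latent geometries can be made to disagree.

## The temporally discounted learner

The learner maintains discounted transition counts ñ. When the walk moves
into node j at time t+1, every past position t−Δt deposits
`exp(−β·Δt)/Z` on ñ[x(t−Δt), j]. The normaliser Z is taken as the finite
geometric sum of the weights, so each observed transition adds exactly
unit mass; this preserves the count interpretation (total mass after T
transitions is T) and makes β → ∞ reduce to exact transition counting.
The finite-time estimate Â(t) row-normalises ñ; rows that have received
no mass predict uniformly (1/n), which also defines the anticipation on
trial 2 as 1/10 rather than discarding early trials. The infinite-time
closed form is Â = (1−e^(−β)) A (I−e^(−β)A)^(−1); the implementation
solves the linear system directly and is validated against the truncated
geometric-series expansion to 1e−8.

Implementation detail: the update has an O(n) recursion (a per-node
"presence" vector decayed by e^(−β) each step), so a full anticipation
series costs O(T·n) rather than O(T²). A jit-compiled scalar kernel is
used when numba is available; a vectorised multi-β path evaluates the
whole search grid in one sweep. Both paths are tested against the literal
O(t)-per-step update.

### Fitting β

Reaction times are first cleaned (rt < 50 ms, rt > mean + 2 SD computed on
the pre-exclusion table, or incorrect → dropped) and residualised by OLS
on trial, stage (250-trial block), finger, hand-transition, and recency
(log trials since the current stimulus last appeared, capped at 10; first
occurrences use the cap). For a single subject the multi-participant
mixed model with random slopes collapses to OLS. The full stimulus
sequence always drives the learner's counts; excluded trials only drop
out of the regression.

For a candidate β, r0 and r1 have a closed-form least-squares solution, so
the fit is a 1-D minimisation of the root-mean-square prediction error:
evaluate the 100-point logarithmic grid on [1e−4, 10], then run gradient
descent from the grid minimum in log β (central finite differences with
step 1e−4, backtracking halving line search with at most 50 halvings, at
most 500 iterations) until |gradient| < 1e−6. Searches that collapse
below β = 1e−6 or escape above β = 1000 are flagged as extreme
(status "zero" / "infinite") and are reported as missing values in any
downstream statistic, never as numeric 0/∞. Fits require at least 50
usable trials. Descent is run in log β because the objective's curvature
is far more uniform on that scale; it only ever accepts improvements, so
the returned objective is never worse than the best grid point.

β is weakly identified at the low end: the RMSE profile flattens as β → 0
(anticipation carries little variance), so single-run estimates below
~0.1 scatter widely. The recovery benchmark reflects this: medians over
20 simulated learners recover β ∈ {0.05, 0.2, 1.0} in order, with typical
median relative error ~20% at 0.05 and a few percent at 0.2 and 1.0.

## Representational similarity analysis

Trials are truncated to a common length L = floor(min rt · fs), floored at
200 ms (shorter trials are discarded): stimulus alignment keeps the first
L samples, response alignment the last L, middle alignment the first
⌈L/2⌉ and last ⌊L/2⌋. Per channel, the RDM entry for conditions (a,b) is
the leave-one-out cross-validated squared Euclidean distance: over folds
k, the held-out-trial difference is projected on the training-mean
difference, `(μ_a^{−k} − μ_b^{−k})·(x_a^k − x_b^k)`, averaged over folds
and divided by the feature count (per-sample units). Folds pair the k-th
trial of each condition in position order; the shorter condition's index
cycles. Cross-validation makes the estimator unbiased at zero for
identical condition means — entries can legitimately be negative.

Template correlations use Pearson on the 45 strictly-lower-triangle
pairs; correlations against similarity templates (Â, A) are multiplied by
−1 so that positive always means "geometry matches". The null reorders
the data trials circularly at a random split s ∈ [1, T−1] (labels fixed),
preserving autocorrelation; s = 0 and s = T are excluded so every null
differs from the observed ordering. Because all inner products in the
estimator live in the trial Gram matrix, null RDMs are recomputed from
the Gram matrix without touching the raw data; this path is tested to be
exactly equal to a literal rotation of the data array. A channel is
selected for the latent space when its Â-correlation beats ≥95 of 100
nulls *and* exceeds its correlation with the exact latent space A; visual
selection uses the null criterion only. With these thresholds the
per-channel false-positive rate is close to, but below, 5% by
construction — consequently, in a 20-channel array with 3 structured
channels, the probability that the selected set is *exactly* the planted
set is only (1−p)^17 ≈ 0.4–0.65 per run even at perfect sensitivity.
The benchmarks therefore report sensitivity (≥0.9 required) and the
false-positive rate separately from exact-support counts.

## Geometry

Neural RDMs are genuine squared-Euclidean matrices, so classical
(Torgerson) MDS applies: double-centre −½·J·D²·J, eigendecompose, scale
the top eigenvectors by √λ. Slightly negative eigenvalues (a by-product
of cross-validation noise) are excluded, with zero-padding and a warning
if fewer than two nonnegative eigenvalues remain. Estimated latent
spaces are similarity matrices, not distances, so they are embedded by
PCA instead: the matrix diagonal is zeroed (self-transitions never occur
in the task and carry no information about node geometry; for an RDM this
is a no-op), columns are centred and scaled to unit variance, and the
rows are projected on the first two principal axes.

Module discriminability is the resubstitution loss of a two-class linear
discriminant on the 10 embedded points (10 points cannot support held-out
evaluation). The sklearn `svd` solver is used because exactly symmetric
analytic estimates produce duplicated coordinates whose within-class
covariance is rank-deficient; a ridge-regularised fallback handles fully
degenerate inputs. On the modular graph this loss exhibits a sharp regime
change: 0 for β ≳ 0.15 and 0.4–0.6 below, with exactly the four boundary
nodes {0,4,5,9} misclassified through most of the low-β regime — the
diagonal-zeroing convention above is what exposes this boundary-node
flip; with the diagonal retained the modules are separable at every β.

## Dynamics

Sliding windows are 1-based and inclusive: width 500 and step 100 over
1000 trials give starts {1, 101, …, 501} — six blocks. Windowed RDM
correlations reuse the full-data trial length so values are comparable
across windows, and are additionally reported normalised by the
channel's full-data value. Windowed β refits residualise per window.
Convergence curves correlate the strictly-lower triangles of Â(t) and the
closed-form Â at every trial (undefined before trial 3), averaged over
walks; larger β converges faster, and at β = 1 the 1000-trial correlation
exceeds 0.97.

## Recording quality control

Channel metrics: line length (summed |first difference|, whole recording,
unnormalised), kurtosis z-scored across channels, and PSD dissimilarity
(mean of 1 − Spearman rank correlation of Welch spectra against every
other channel, z-scored). Channels are flagged at line length > 3× mean,
kurtosis z > 1.5, or dissimilarity z > 1.5; constant channels are flagged
outright. Note these are relative thresholds: in any cohort of channels
some fraction will sit past a 1.5-z cut.

The discharge detector downsamples to 200 Hz, band-passes 10–60 Hz
(4th-order zero-phase Butterworth), and squares the analytic-signal
magnitude. In 5-s windows with 4-s overlap the threshold is
k0 × (mode + median) of the envelope with k0 = 3.65 (configurable; the
scaling form follows the envelope-distribution-modelling convention of
this detector family — the mode is estimated from a 64-bin histogram
since no mode exists for continuous data). Overlapping window decisions
are OR-ed per sample; each supra-threshold excursion yields one event at
its envelope peak. The spatial filter keeps an event only if at least
three other channels have events within ±50 ms. This thresholding scheme
presumes a rhythm-dominated background whose band-limited envelope is
tight; on a purely Gaussian background the envelope is exponential and
any mode+median threshold sits inside the noise tail, which is why the
synthetic benchmark (below) includes an ongoing rhythm.

## Synthetic data

`gen_behavior` draws a walk, computes the true anticipation series at a
configured β, and emits rt = r0 + r1·a(t) + γ·recency + ε. Defaults:
r0 = 0.75 s (clinical cohorts respond near 0.7 s), r1 = −0.25 s (full
anticipation speeds responses by 250 ms), Gaussian ε with sd 0.06 s
(≈|r1|/4, small enough that β is recoverable; a log-normal option exists
for heavy-tailed realism), γ = 0.05 s per log-trial so that
residualisation matters in tests, accuracy 0.97, 1000 trials.

`gen_neural` plants a chosen similarity template into selected channels:
the template is affinely converted to a dissimilarity, embedded by
eigendecomposition so that the *squared* distances between per-node mean
patterns are an affine image of the template (a Lingoes additive constant
lifts any negative eigenvalues — Pearson correlations are unaffected by
the affine shift, so a noiseless structured channel correlates with the
template at r ≈ 1). Patterns occupy the first 200 ms of each trial — the
portion guaranteed to survive stimulus-aligned truncation — mixed across
samples by a per-channel random orthonormal matrix; all other samples and
channels are unit white noise. SNR is the ratio of the mean pattern norm
to the expected noise norm over the pattern samples. A time-constant
pattern per channel was rejected: it would make each channel's geometry
one-dimensional, and a 10-node template cannot embed in one dimension.

`gen_ied_recording` builds backgrounds of pink noise mixed with an
amplitude-modulated 18-Hz rhythm (see above for why a rhythm is needed),
and injects a windowed biphasic 70-ms transient (1.5 cycles ≈ 21 Hz, well
inside the detection band) synchronously on a random subset of ≥4
channels, at peak amplitude snr × background sd, with a 0.3-s refractory
margin between spikes.

What the synthetic data do *not* emulate: evoked-potential waveshape,
trial-to-trial latency jitter, 1/f structure within epochs, correlated
noise across channels, non-stationary learning (β is constant within a
run unless windows are simulated separately), and realistic discharge
morphology variability. Passing benchmarks therefore validate the
estimators' contracts — calibration, unbiasedness, recovery under the
assumed generative structure — not performance on clinical recordings.

## Benchmark problem sizes

The packaged benchmarks (shared by the test suite and
`scripts/acceptance.py`) use: β recovery — 20 simulated learners per true
β at 1000 trials, noise sd |r1|/4; RSA calibration — 200 noise channels,
300 trials, 100 permutations; planted recovery — 20 runs of 20 channels
(3 structured) at SNR 2, 1000 trials; distance bias — 200 simulations of
two 10-trial conditions; convergence — 20 walks of 1000 trials;
discharge detection — 20 channels, 120 s, 30 spikes at SNR 5. All
randomness flows from explicit seeds; identical configurations reproduce
byte-identical outputs (HDF5 written without timestamps).

## Known limitations

- β below ~0.1 is weakly identified from 1000 trials; windowed (500-trial)
  refits are correspondingly noisy, and extreme-status windows are
  reported missing rather than imputed.
- The maximum deviation max|Â(β) − A| is not perfectly monotone in β at
  the very low end on the modular graph (cross-module entries undershoot
  the uniform value near β ≈ 0.05) — a property of the closed form, not
  of the implementation.
- Multi-subject mixed-effects modelling is out of scope; the
  residualisation hook accepts any externally computed residual series.
- The IED detector's k0 ↔ (mode+median) convention is configurable
  because detector families differ; the default multiplicative form is
  validated only on the synthetic benchmark.
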