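# latentlearn

Tools for studying how people learn the *latent graph* behind a sequence of
stimuli, and where neural activity reflects the map they build.

In a probabilistic serial reaction time task, stimuli follow a random walk
on a hidden 10-node, degree-4 graph (either a two-module "community" graph
or a ring lattice). Learners respond faster to transitions they anticipate,
so their reaction times expose their internal estimate of the graph. This
package implements:

- **A temporally discounted learner.** Transition counts are accumulated
  with exponentially decaying memory: when the walk moves to a new node,
  every past node deposits mass on the (past node → new node) transition,
  weighted by `exp(-β·Δt)`. The single parameter β sets the steepness of
  discounting. In the infinite-data limit the learner's estimate of a
  row-stochastic transition matrix `A` is

      Â = (1 − e^(−β)) · A · (I − e^(−β)·A)^(−1),

  a geometric mixture of the powers of `A`: β → ∞ recovers `A` (exact
  counting), β → 0 smears all transitions to the uniform matrix.
- **Fitting β from behavior.** The learner's anticipation of the observed
  transition at trial *t*, `a(t) = Â_{x(t−1),x(t)}(t−1)`, predicts the
  reaction-time residual through `r̂(t) = r0 + r1·a(t)`; β is estimated by
  minimising the RMSE of that prediction (100-point log grid on
  [1e−4, 10], then gradient descent), after trial filtering and OLS
  residualisation against motor/recency nuisance covariates.
- **Representational similarity analysis.** Per recording channel,
  leave-one-out cross-validated Euclidean RDMs between the 10 evoked
  stimulus patterns, correlated with the estimated latent space Â, the
  exact latent space A, and a visual (screen-distance) control template.
  Channels are selected against a circular-shift permutation null that
  preserves the autocorrelation of the recording.
- **Geometry and dynamics.** Classical-MDS / PCA embeddings of the
  condition geometry, linear-discriminant module separability, sliding
  window (500-trial blocks, 100-trial step) template correlations and β
  refits, and simulated convergence of the finite-time estimate Â(t) to Â.
- **Recording QC.** Channel rejection (line length, kurtosis, PSD
  dissimilarity) and Hilbert-envelope interictal-discharge detection with a
  multichannel spatial filter and trial rejection.
- **Synthetic data.** Generators for behavior (walks plus model-generated
  reaction times), evoked epochs that embed any similarity template at a
  controlled SNR, and continuous recordings with planted discharges — so
  every analysis can be validated end to end against known ground truth.

## Worked example

Simulate a learner with β = 0.2 on the modular graph, preprocess its
reaction times, and fit the model:

```python
from latentlearn import (SynthConfig, gen_behavior, filter_trials,
                         residualize_rt, TemporalDiscountingModel,
                         transition_matrix, build_modular_graph)

cfg = SynthConfig(beta_true=0.2, seed=42)
x, trials = gen_behavior(cfg)                      # walk + reaction times
resid = residualize_rt(filter_trials(trials))      # nuisance-free residuals
model = TemporalDiscountingModel(
    x, resid, transition_matrix=transition_matrix(build_modular_graph()))
print(model.fit().summary())
```

```
Temporal discounting model (maximum entropy learner)
========================================================
n usable trials                      939
status                          interior
beta (discount steepness)         0.4856
r0 (intercept, s)                 0.0264
r1 (anticipation slope, s)       -0.1474
RMSE (s)                          0.0576
========================================================
```

939 of 1000 trials survive filtering (incorrect, <50 ms, or >2 SD above
the mean). The fitted β (0.49 here; single-run estimates of a weakly
identified parameter scatter around the true 0.2) comes with a negative
anticipation slope r1 — well-predicted stimuli are answered ~150 ms faster
at full anticipation — and an RMSE of 58 ms on residual reaction times.
`results.latent_estimate()` then returns the learner's estimated map Â,
whose 2-D embedding separates the two graph modules perfectly at this β
(`lda_module_loss(...) == 0`).

A complete synthetic-to-analysis run (behavior → fit → channel selection →
geometry → dynamics) is one call:

```sh
latentlearn pipeline run --config run.json
```

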