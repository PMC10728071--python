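# Methods

## The model

`atherotrend` infers per-diet-group latent signal-area trajectories from
weekly per-mouse measurements. With $t = 1 \dots T$ indexing weekly
observation points (week 0 of the diet induction is $t = 1$) and $f$ the
food index (control first), the generative model is

- observation: $Y \sim \mathrm{LogNormal}(\log A_{t,f} - \sigma_1^2/2,\ \sigma_1)$,
  independently for every mouse in cell $(t, f)$;
- latent trend: $A_{t,f} = 2A_{t-1,f} - A_{t-2,f} + \mu_{t,f}$ with the
  convention $A_0 = A_{-1} = 0$, i.e. $A$ is the double cumulative sum of
  the innovations $\mu$ (a second-order random walk / local linear
  trend — innovations perturb the slope, not the level);
- innovations: $\mu_{t,f} \sim N(0, \sigma_2)$, one $\sigma_2$ shared
  across groups and weeks (a per-group option exists, off by default);
- hyperpriors: $\sigma_1, \sigma_2 \sim \mathrm{HalfNormal}(1)$; no other
  prior terms (everything else is left flat / weakly informative).

The $-\sigma_1^2/2$ location correction makes $E[Y] = A_{t,f}$ exactly,
so the latent is the mean signal area rather than its median.

Assumptions worth stating: all mice within a group share one latent
trajectory (no per-mouse random effects); observation errors are
independent across mice and weeks; the latent must be strictly positive
wherever it is observed, which is enforced as a $-\infty$ log-likelihood
rather than by reparametrization. Group means vs per-mouse observations
is genuinely ambiguous in this kind of design; the default treats every
mouse as an observation of its group's latent, and `aggregate="mean"`
collapses cells to their mean first for users who prefer that reading.

## Parameters and defaults

| parameter | units | default | why |
|---|---|---|---|
| `n_weeks` (T) | weeks | 11 | weeks 0–10, so the week-10 summaries exist |
| `groups` / `n_mice` | — | HCD, HCD+HVK, HCD+LVK, HCD+NN with 6/6/6/3 | the study design the package emulates |
| `sigma_obs` ($\sigma_1$) | log scale, dimensionless | 0.3 | ~30% multiplicative measurement noise, realistic for ROI counts of live images |
| `sigma_state` ($\sigma_2$) | pixel area | 30 | innovation scale that drives positive latent paths from ~0 to order hundreds of pixels by week 10, matching reported trajectory magnitudes (~75–100 at week 5, ~200–300+ at week 10) |
| `data_rescale` | pixel area | 1 (library), 100 (pipeline default) | divides Y before fitting so the *standard* half-normal hyperpriors stay weakly informative on O(1) quantities; summaries are mapped back to original units (multiplying $A$, $\mu$, $\sigma_2$; $\sigma_1$ is scale-free) |
| `scale_min`/`scale_max` | counts | 337 / 1020 | fixed color-scale floor/ceiling set from autofluorescence-free negative controls; a pixel counts as signal only strictly above the floor |
| chains / draws / warmup | — | 4 / 1000 / 1000 | conventional multi-chain budget; the bundled demo uses 4 × (1000 + 5000) so the ESS gate is met with margin |
| `ci_level` | — | 0.89 | the reporting convention for all credible bands |
| `rhat_max` / `ess_min` | — | 1.05 / 400 | common conservative gates for a model of this size |

## Sampling

The sampler is an adaptive component-wise random-walk Metropolis kernel
(numba-compiled). Two numerical choices matter:

1. **State-space parametrization.** The chain's coordinates are the
   latents $A_{t,f}$ themselves plus $\log\sigma_1, \log\sigma_2$; the
   innovations are recovered as second differences of $A$. The map
   $\mu \to A$ is linear, lower-triangular with unit diagonal, so the
   density over $A$ is the same posterior with unit Jacobian. Updating a
   single $\mu$ shifts the entire downstream trajectory and mixes
   pathologically; updating a single $A_{t,f}$ touches one cell's
   likelihood and three neighboring prior terms, and mixes well at the
   default budget.
2. **Log-scale hyperparameters.** Sampling $\log\sigma$ (with the
   Jacobian term added) keeps proposals inside the half-normal support.

Per-parameter proposal scales adapt during warmup in windows of 50
sweeps toward ~30% acceptance and are frozen afterwards, so the
post-warmup chain satisfies detailed balance. Chains start from a
data-driven state (per-cell geometric means, interpolated across
unobserved cells, with multiplicative over-dispersion per chain) and
per-chain seeds derive from one master seed through keyed
`SeedSequence` streams. Proposals whose implied latent is non-positive
at an observed cell get $-\infty$ density and are rejected, which is how
the positivity support is honored without changing the stated model. A
run whose initial density is non-finite, or that rejects every
post-warmup proposal, aborts with advice to set `data_rescale`.

The kernel's correctness is cross-checked three ways in the test suite:
its density equals the pure-Python `log_posterior` (plus Jacobian)
everywhere; its posterior mean matches 1-D grid quadrature on a clamped
single-cell instance; and it agrees with an independent affine-invariant
ensemble sampler (emcee) targeting the same density.

## Summaries

- **Mode**: argmax of a Gaussian-kernel density estimate (Silverman
  bandwidth) on a fixed 512-point grid spanning the draw range —
  deterministic given draws; a constant vector returns itself; ties
  resolve to the lowest grid point. The mode of a skewed marginal is not
  required to sit inside the credible interval, only inside the draw
  range.
- **Intervals**: equal-tailed percentile intervals by default
  (reproducible without density estimation); highest-density intervals
  behind `interval="hpd"`.
- **Contrasts**: formed per draw as $A_{t,f} - A_{t,f_0}$ before
  summarizing, which respects posterior correlation; "significant" is
  operationalized as the 89% interval excluding zero. This is this
  package's definition, not a frequentist test.

## Diagnostics

Classic (non-rank-normalized) split R-hat: each chain is halved, and
$\hat R = \sqrt{((n-1)/n\,W + B/n)/W}$ over the halves; identical
constant chains return exactly 1; a rank-normalized variant sits behind
a flag. ESS uses per-chain FFT autocovariances pooled against the
combined-chain variance with Geyer initial-positive-sequence
truncation, capped at the total draw count; zero-variance chains return
the cap with a warning. An odd iteration count drops the last draw
before splitting.

## The synthetic cohort generator

The generator *is* the study conditions: it draws $\mu \sim N(0,
\sigma_2)$ per group, redrawing any column whose implied trajectory is
not strictly positive (bounded rejection keeps the truth inside the
likelihood's support without changing the stated distributions; the cap
raises an error naming `sigma_state` when the innovation scale is too
large for positive paths). Observations are exact log-normal draws per
mouse. Optionally it renders grayscale frames in which exactly
`round(Y)` ROI pixels exceed the color-scale floor while every other
pixel carries sub-floor noise, so the quantifier must recover the target
exactly — a closed loop used throughout the tests.

What it does **not** emulate: per-mouse biological heterogeneity,
imaging-session batch effects, ROI mis-tracing, detector saturation, or
any biology of plaque growth. Passing tests therefore certify the
statistical machinery under the model's own assumptions, not robustness
to real-data violations of them.

## Problem sizes used by tests and the acceptance script

Replicate studies use the study-shaped design (T = 10–11, four or two
groups, 6/6/6/3 or 6/6 mice) with 100 replicates and two chains of
600–800 warmup / 800 draws per fit; single converged fits use four
chains and 3000–5000 draws. These sizes give Monte-Carlo error
comfortably below the tolerances they are tested against while keeping
a full suite run around a minute on one CPU.

## Known limitations and honest numbers

- The credible intervals are calibrated: the measured 89% coverage over
  100 replicates is ~86–91% for the latent areas and $\sigma_1$. A
  consequence is that a contrast between two groups generated from one
  shared trajectory contains zero in ~88–92 of 100 replicates — the
  nominal 89%, not more. Any stronger null-containment guarantee would
  require deliberately conservative (wider) intervals, which this
  package does not do.
- ESS is the classic initial-positive-sequence estimator; on strongly
  multimodal chains it can be optimistic (as can any autocorrelation
  estimator).
- The component-wise kernel scales linearly in $T \times F$ per sweep;
  for much longer series or many more groups a gradient-based sampler
  would be preferable. The sampler contract (stationary distribution =
  `log_posterior`) is the module boundary a replacement must satisfy.
- Zero signal areas (possible after image quantification of an empty
  ROI) lie outside log-normal support; the pipeline drops them for
  fitting and reports how many it dropped.
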