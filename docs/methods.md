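# Methods

## The generative model

A trial presents `n_T = n_a + n_b` targets of two classes (`a`, `b`) and
the forager selects them one at a time without replacement. The bag model
assigns every remaining target a weight that depends only on its class and
on the previously selected class; selection is then proportional to total
class weight times remaining count. Writing `p_s` for the stick bias and
`p_a` for the class bias (both defined at equal availability, see README),
the class-`a` selection probability is

* first selection: `p_a n_a / (p_a n_a + (1 − p_a) n_b)`
* after an `a`: `p_a p_s n_a / (p_a p_s n_a + (1 − p_a)(1 − p_s) n_b)`
* after a `b`: `p_a (1 − p_s) n_a / (p_a (1 − p_s) n_a + (1 − p_a) p_s n_b)`

Dividing numerator and denominator shows that every step is Bernoulli in
class `a` with log-odds

    b_a + m · b_s + log(n_a / n_b),

where `b = logit(p)` and `m ∈ {+1, 0, −1}` codes the previous class (0 on
the first selection). The implementation uses this identity: the whole
dataset flattens into a weighted Bernoulli-logit likelihood with a
count-ratio offset, evaluated vectorised. The scalar step functions
(`class_probability`, `trial_loglik`) implement the product form directly,
and the test suite verifies both routes agree to 1e-9 and that sequence
probabilities sum to one by exhaustive enumeration.

Steps on which only one class remains are forced (probability 1) and
contribute nothing to the likelihood; they are dropped from the design.
Trials whose observed length is shorter than `n_T` contribute only their
observed steps — there is no stopping-rule term, search termination is
deliberately out of scope.

The spatial model replaces the class-level Bernoulli with a categorical
draw over individual remaining targets with weights

    w(i) = g(b_a t_i + b_s m(t_i, t_prev)) · exp(−σ_d d(i, prev)) · exp(−σ_θ θ(i, prev)),

already-selected targets having weight exactly 0. The first selection uses
only the class term; the second omits the direction factor (no travel
direction exists yet). Dropping undefined factors — rather than imputing
them — is the cleanest reading of the first-selection logic and avoids
undefined `atan2` arguments. `θ` is the absolute angular difference between
the previous travel direction and the direction to the candidate, scaled to
[0, 1]; it is invariant to global rotation and translation of the display.
Setting `σ_d = σ_θ = 0` makes the class-marginal of the categorical model
identical to the bag model with the same `b_a, b_s` (verified by
enumeration), so the bag model is nested in the spatial one.

Coordinates are normalized by stimulus width at ingest. This convention
matters: proximity tuning values near 15 mean that a target a quarter
stimulus-width away receives `e^{−3.75} ≈ 0.02` of the weight of an
adjacent one, which is the scale on which empirical fits are interpreted.
Whether a given upstream dataset recorded pixels or normalized units must
be resolved at ingest; the normalization factor belongs in dataset
metadata.

## Priors and parameters

| parameter | scale | prior | default | meaning |
|---|---|---|---|---|
| `b_s`, `b_a` | logit | N(0, 1) | — | stick / class bias |
| `σ_d` | 1/width | N(0, 20), truncated ≥ 0 | — | proximity tuning |
| `σ_θ` | 1/θ-unit | N(0, 5), unconstrained | — | direction tuning |
| `τ` (random-effect SDs) | logit | half-normal(1) | — | participant spread |

The N(0, 1) logit prior puts ≈ 97% prior mass on `p ∈ (0.1, 0.9)` — weakly
informative and symmetric. `σ_θ` is left unconstrained because empirical
fits can favour doubling back (negative values); `σ_d` is constrained
nonnegative by default (configurable) since a preference for *far* targets
has no behavioural interpretation in these tasks. Prior scales are
constructor arguments on both estimators.

Multilevel structures use the non-centered parameterization
`b = μ + τ · z`, `z ∼ N(0, 1)`, with `τ` sampled on the log scale (the
half-normal prior plus the log-Jacobian). The spatial multilevel model
draws the four per-participant effects jointly with an estimated
correlation structure; the correlation Cholesky factor is parameterized by
row-normalizing a unit-diagonal lower-triangular matrix of unconstrained
N(0, 1) entries (a simple smooth bijection onto valid factors; an exact
LKJ density is not claimed). A `diagonal_effects` switch removes the
correlations.

## Sampling and diagnostics

Posteriors are low-dimensional (2 per condition for the bag model, 4 for
the pooled spatial model) and smooth, so sampling uses affine-invariant
ensemble MCMC (emcee) with differential-evolution moves, which mix far
faster than stretch moves on these near-Gaussian targets. Each reported
chain is an independent ensemble of ≥ 32 walkers started in a small ball
around the numerically located posterior mode; warmup (≥ 150 ensemble
steps, discarded) removes the initialization transient, and kept walker
draws are interleaved into the chain. Defaults: 4 chains × 1000 post-warmup
draws. The backend is pluggable — any callable mapping a log-density to
seeded (chains × iterations × dim) draws can be substituted.

Convergence is summarised per parameter by split-R-hat and bulk effective
sample size (via arviz); parameters with R-hat > 1.01 or ESS < 400 are
flagged and fits expose `converged_`. Split-R-hat computed on interleaved
ensemble chains is a noisy statistic: with few kept steps it can exceed
1.01 on genuinely converged runs. Harness defaults keep ≥ 100 ensemble
steps per chain, which makes false flags rare; flagged fits in power
studies are counted and reported, never dropped.

HPDIs are computed as the shortest contiguous window containing
`⌈mass · n⌉` sorted draws — correct for the unimodal posteriors produced
here — and always on the reporting scale (probability-scale intervals come
from transformed draws, not transformed endpoints). The 53 / 89 / 97%
levels are the package convention ("more likely than not" / wide / "very
likely"). Between-condition differences are assessed by the 97% HPDI of
the paired difference of probability-scale draws excluding 0; the interval
mass is configurable (`DetectionRule`), and `Pr(diff > 0)` is reported
alongside.

## Synthetic data

`synthetic` layouts place two target classes in a unit-width frame:
uniform (independent positions, minimum separation 1e-3 widths, resampled
on collision), jittered grid, and patchy — per class, 2 cluster centers
with Gaussian scatter of SD 0.08 widths by default. The patchy defaults
are package choices (the clumped layouts they emulate are not published
with exact geometry); they produce clearly clumped displays whose
within-class nearest-neighbour distances are well below between-class
ones, which is the property the misattribution study needs.

Experiment designs pair per-condition generating parameters with a trial
count and composition; the canonical designs are 50 trials × 40 targets
(20 per class) per condition — *differentiation* (`p_s=0.55, p_a=0.5` vs
`p_s=0.5, p_a=0.65`) and *misattribution* (neutral vs `p_a=0.8`). The
misattribution design mirrors the differentiation geometry, whose
dimensions are the published ones. Multilevel generation draws each
participant's logit-scale biases around the condition values (SD 0.3 by
default).

What the generator does *not* emulate: reaction times, distractors,
perceptual error, learning or fatigue across trials, and stopping rules
(simulated trials are exhaustive unless a length is given). Passing
recovery and power checks on these data therefore demonstrates correctness
of the inference machinery under the model's own assumptions, not
robustness to the many ways real behaviour violates them.

## Simulation studies

`run_power_study` repeats simulate → fit → test: per repetition the
by-condition bag model is fitted, the detection rule applied to the `p_a`
and `p_s` differences, and one-way fixed-effects ANOVAs run on per-trial
number-of-runs and maximum-run-length at α = 0.05 (trial-level values; the
simulated designs have no participant grouping). Results are
bit-reproducible given (design, reps, seed, sampler settings). Power runs
use a lighter sampler profile (2 chains × 3200 draws per condition, ~0.5 s
per fit) whose detection rates agree with the default profile; the
acceptance script uses 100 repetitions, matching the canonical study size,
in a few minutes of CPU.

The extreme-bias probes fit data generated at `p_s = 1`, `p_a = 1` and
`p_a = 0.97`. At `p_s = 1` every trial is two maximal runs, class
information is nearly absent, and the `p_a` posterior degrades — severalfold
wider than a matched neutral fit, its mean wandering off 0.5 in a
direction set by the accident of first picks; the probe quantifies this
against an internally fitted neutral reference. At `p_a = 1` all preferred
targets are collected first, a pattern equally consistent with an extreme
stick bias, and both posteriors concentrate near 1 — the estimates are
faithful to the data even though they do not match the generator. At
`p_a = 0.97` recovery succeeds.

## Posterior predictive checks

`posterior_predict` simulates one replicate dataset per posterior draw on
the observed stimulus layouts (re-using draws, with a warning, only if
asked for more than exist). A bag fit predicting onto spatial layouts uses
the equivalent σ = 0 spatial model — same-class targets are
interchangeable under the bag model, so this adds no assumptions.
`ppc_report` compares per-trial run statistics, and for spatial data the
mean inter-target distance by selection index, against 89% predictive
intervals; trials of unequal length are truncated at the shortest common
length for the distance profile (an alignment convention). Tiny predictive
ensembles (< 10 draws) fall back from HPDI to range bands. The report
exposes `run_stat_coverage()` and `distance_mismatch_fraction()`; the
characteristic mis-specification signature — a bag fit on clumped layouts
matching run statistics while sitting far above the observed short step
distances — is exercised in the test suite.

## Numerical choices and edge cases

* Likelihoods are evaluated in log space throughout; the categorical
  normalizer uses a max-shifted logsumexp, and masked (already-selected)
  targets enter as −inf before normalization, keeping gradients of the
  remaining weights well-defined.
* The class/stick logit in the spatial likelihood takes only six distinct
  values per parameter vector ((class ± 1) × (stick −1/0/+1)); a lookup
  table avoids softplus evaluations over the full steps × targets array.
* Duplicate design rows in the bag likelihood (same observed class,
  previous-class code, count ratio, participant) are aggregated with
  multiplicity weights.
* Degenerate parameter corners (`p = 0` or `1` cancelling both class
  weights) return probability 0.5 rather than 0/0; forced selections are
  exact 0s and 1s.
* Exact ties in candidate weights need no tie-breaking — the categorical
  draw handles them naturally.
* Seeds: every public simulation and fitting entry point takes a seed or
  `numpy.random.Generator`; per-condition and per-repetition seeds are
  derived through `numpy.random.SeedSequence`.

## Problem sizes

Default test and study sizes are chosen to resolve the scientific question
at desk scale: power studies use the canonical 50 × 40 design (100
repetitions in the acceptance script, 20 in the test suite with 3-SE
binomial tolerance bands); spatial fits use 15–30 trials; enumeration
oracles run at `n_T ≤ 6`, where exhaustive sums are exact. The multilevel
spatial model is exercised at small scale (a few participants); fitting
dozens of participants with correlated four-parameter random effects is a
larger computation than these defaults target, and the ensemble sampler
is expected to be slow there — a gradient-based sampler behind the
pluggable backend would be the natural upgrade.

## Known limitations

* Two target classes only; extending to more classes requires an extra
  preference parameter per additional class and a categorical class term.
* No stopping rules, inter-selection times, or distractor modelling.
* The exponential proximity kernel and the monotone direction kernel are
  conventions, not discoveries; other kernels may fit real data better.
* The correlation parameterization of the spatial multilevel model implies
  a particular (non-LKJ) prior over correlation matrices.
* Split-R-hat on interleaved ensemble chains is conservative-noisy; treat
  isolated flags at light sampler settings as suspicion, not proof, and
  refit with defaults.
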