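# bagforage

Bayesian sampling-without-replacement models of visual foraging.

In a foraging task an observer collects many targets of two classes, one at
a time, from a single display. The classical way to analyse the resulting
selection sequences is through *run statistics* — the number of runs of the
same class, the maximum run length, the switch rate. These statistics are
interdependent, depend on how many targets of each class remain, and say
nothing about *why* runs arise. `bagforage` instead models the sequence
generatively, as weighted sampling without replacement from the remaining
target pool ("pulling balls out of a bag"), and estimates interpretable
selection biases by MCMC:

* **stick bias** `p_s = Pr(t_i = t_{i-1} | n_a = n_b)` — the tendency to
  repeat the previous target class (`p_s < 0.5`: a switching preference);
* **class bias** `p_a = Pr(t_i = a | n_a = n_b)` — the preference for one
  class over the other;
* and, in the spatial variant, **proximity tuning** `σ_d` and
  **direction/momentum tuning** `σ_θ`.

With `n_a` and `n_b` targets of each class remaining, the probability of
selecting class `a` after an `a` is

    Pr(t_i = a) = p_a p_s n_a / (p_a p_s n_a + (1 − p_a)(1 − p_s) n_b)

(and symmetrically after a `b`; on the first selection only `p_a` applies).
The spatial model replaces the class-level Bernoulli with a categorical
distribution over individual remaining targets, with weights

    w(i) = g(b_a t_i + b_s m(t_i, t_prev)) · e^{−σ_d d(i, prev)} · e^{−σ_θ θ(i, prev)}

where `g` is the inverse logit, `t_i = ±1` codes the class, `m = ±1`
indicates a class repeat, `d` is the distance to the previous selection in
stimulus-width units and `θ ∈ [0, 1]` is the angular deviation from the
current direction of travel (0 = straight on, 1 = doubling back; negative
`σ_θ` therefore favours reversals). Biases are fitted on the logit scale
with N(0, 1) priors; posteriors are summarised with 53 / 89 / 97% highest
posterior density intervals (HPDIs). Pooled, by-condition, and multilevel
(per-participant random effects) structures are available, as
scikit-learn-style estimators that compose with sklearn tooling.

The package also ships the surrounding laboratory: synthetic stimulus
layouts (uniform, grid, patchy), full experiment simulators, power-study
harnesses comparing the Bayesian decomposition against run-statistic
ANOVAs, extreme-bias probes, and posterior predictive checks on run
statistics and inter-target distances.

## Worked example

Two simulated conditions that classical run statistics cannot tell apart —
one with a small stick bias (`p_s = 0.55`), one with a small class bias
(`p_a = 0.65`) — 50 trials of 40 targets each:

```python
import numpy as np
from bagforage import (BagForagingModel, BagParams, Dataset,
                       simulate_bag_trial, prob_positive, hpdi)

rng = np.random.default_rng(0)
trials = []
for cond, params in [("stick", BagParams(p_s=0.55, p_a=0.5)),
                     ("classbias", BagParams(p_s=0.5, p_a=0.65))]:
    for i in range(50):
        trials.append(simulate_bag_trial(20, 20, params, seed=rng,
                                         condition=cond, trial_id=f"t{i+1}"))
data = Dataset(trials)

model = BagForagingModel(structure="by_condition", random_state=1).fit(data)
for name in ("p_s[stick]", "p_s[classbias]", "p_a[stick]", "p_a[classbias]"):
    iv = model.posterior_.hpdi(name, 0.97)
    print(f"{name:15s} mean {model.posterior_.mean(name):.3f}   "
          f"97% HPDI [{iv.lower:.3f}, {iv.upper:.3f}]")

diff_ps = (model.posterior_.get("p_s[classbias]")
           - model.posterior_.get("p_s[stick]"))
diff_pa = (model.posterior_.get("p_a[classbias]")
           - model.posterior_.get("p_a[stick]"))
for label, d in [("p_s", diff_ps), ("p_a", diff_pa)]:
    iv = hpdi(d, 0.97)
    print(f"difference in {label}: 97% HPDI [{iv.lower:.3f}, {iv.upper:.3f}]"
          f"   Pr(diff > 0) = {prob_positive(d):.3f}")
```

Output:

```
p_s[stick]      mean 0.533   97% HPDI [0.507, 0.559]
p_s[classbias]  mean 0.484   97% HPDI [0.458, 0.510]
p_a[stick]      mean 0.499   97% HPDI [0.476, 0.524]
p_a[classbias]  mean 0.673   97% HPDI [0.648, 0.695]
difference in p_s: 97% HPDI [-0.087, -0.014]   Pr(diff > 0) = 0.003
difference in p_a: 97% HPDI [0.141, 0.209]   Pr(diff > 0) = 1.000
```

Each condition's generating bias is recovered, and both between-condition
difference intervals exclude 0 — the model attributes the difference to the
right parameter in each case. An ANOVA on the run statistics of these same
data typically finds nothing (the two conditions produce nearly identical
run-length distributions).

## Command line

```sh
bagforage simulate --model bag --pa 0.65 --ps 0.5 --trials 50 --targets 40 \
    --seed 1 --out trials.csv
bagforage runstats --input trials.csv
bagforage fit --model bag --structure by_condition --input trials.csv \
    --seed 1 --out-summary fit.json
bagforage power --design differentiation --reps 100 --seed 1 --out power.json
bagforage ppc --input trials.csv --n-draws 100 --seed 1 --out ppc.json
```

Trial CSVs have one row per selection with columns
`participant,condition,trial,order,class[,x,y]`; `class ∈ {a, b}`, `order`
is 1-based, and coordinates are in normalized stimulus-width units.

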