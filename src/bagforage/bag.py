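"""Non-spatial 'bag' foraging model: weighted sampling without replacement.

Each selection removes one target from the remaining pool. Two biases govern
which class is drawn next:

* ``p_s`` — stick bias: the probability of repeating the previous class when
  both classes are equally available (p_s < 0.5 means a switching preference);
* ``p_a`` — class bias: the probability of picking class ``a`` over ``b``
  when equally available.

With ``n_a`` and ``n_b`` targets of each class remaining, the probability of
selecting class ``a`` is

    first selection:   p_a n_a / (p_a n_a + (1-p_a) n_b)
    after an 'a':      p_a p_s n_a / (p_a p_s n_a + (1-p_a)(1-p_s) n_b)
    after a 'b':       p_a (1-p_s) n_a / (p_a (1-p_s) n_a + (1-p_a) p_s n_b)

Equivalently each step is Bernoulli with log-odds
``b_a + m b_s + log(n_a / n_b)`` where ``b = logit(p)`` and ``m`` codes the
previous class (+1 after 'a', -1 after 'b', 0 on the first step). The scalar
functions below use the product form; the fitting code uses the logistic
form, which vectorizes over all selection steps at once.

Inference uses independent-ensemble MCMC with N(0, 1) priors on ``b_s`` and
``b_a`` (a prior under which p falls in (0.1, 0.9) about 97% of the time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .data import Dataset, Stimulus, TargetClass, Trial
from .inference import MCMCSettings, PosteriorDraws, sample_ensemble

__all__ = [
    "BagParams", "class_probability", "trial_loglik", "dataset_loglik",
    "simulate_bag_trial", "BagForagingModel", "fit_bag",
]


@dataclass(frozen=True)
class BagParams:
    """Stick and class biases on the probability scale."""

    p_s: float = 0.5
    p_a: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.p_s <= 1.0 and 0.0 <= self.p_a <= 1.0):
            raise ValueError("p_s and p_a must lie in [0, 1]")

    @classmethod
    def from_logits(cls, b_s: float = 0.0, b_a: float = 0.0) -> "BagParams":
        return cls(p_s=float(expit(b_s)), p_a=float(expit(b_a)))

    @property
    def b_s(self) -> float:
        return float(logit(self.p_s))

    @property
    def b_a(self) -> float:
        return float(logit(self.p_a))


def class_probability(prev: TargetClass | None, n_a: int, n_b: int,
                      params: BagParams) -> float:
    """Probability that the next selected target is of class ``a``.

    ``prev`` is the previously selected class, or None on the first
    selection. Exhausted classes get probability 0 (resp. 1) exactly.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be nonnegative")
    if n_a + n_b == 0:
        raise ValueError("no targets remain")
    if n_a == 0:
        return 0.0
    if n_b == 0:
        return 1.0
    p_a, p_s = params.p_a, params.p_s
    if prev is None:
        wa, wb = p_a * n_a, (1.0 - p_a) * n_b
    elif prev is TargetClass.A:
        wa, wb = p_a * p_s * n_a, (1.0 - p_a) * (1.0 - p_s) * n_b
    else:
        wa, wb = p_a * (1.0 - p_s) * n_a, (1.0 - p_a) * p_s * n_b
    total = wa + wb
    if total == 0.0:  # degenerate 0/1 parameters cancelling both classes
        return 0.5
    return wa / total


def trial_loglik(trial: Trial, params: BagParams) -> float:
    """Log probability of the observed selection-class sequence.

    Walks the sequence decrementing class counts; -inf if the sequence
    selects an exhausted class (impossible under the model).
    """
    n_a, n_b = trial.stimulus.n_a, trial.stimulus.n_b
    prev = None
    ll = 0.0
    for cls in trial.class_sequence:
        pa = class_probability(prev, n_a, n_b, params)
        p = pa if cls is TargetClass.A else 1.0 - pa
        if p <= 0.0:
            return -math.inf
        ll += math.log(p)
        if cls is TargetClass.A:
            n_a -= 1
        else:
            n_b -= 1
        prev = cls
    return ll


def dataset_loglik(dataset: Dataset, params: BagParams) -> float:
    """Sum of trial log likelihoods over a dataset."""
    return float(sum(trial_loglik(t, params) for t in dataset))


def simulate_bag_trial(n_a: int, n_b: int, params: BagParams,
                       length: int | None = None, seed=None, *,
                       participant: str = "p1", condition: str = "c1",
                       trial_id: str = "t1") -> Trial:
    """Draw one trial from the bag model.

    ``length`` defaults to exhaustive foraging (all targets selected).
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if length is None:
        length = n_a + n_b
    if length > n_a + n_b:
        raise ValueError("trial length exceeds number of targets")
    stim = Stimulus.from_counts(n_a, n_b)
    # targets within a class are interchangeable: ids 0..n_a-1 are class a
    next_a, next_b = 0, n_a
    rem_a, rem_b = n_a, n_b
    prev = None
    picks: list[int] = []
    for _ in range(length):
        pa = class_probability(prev, rem_a, rem_b, params)
        if rng.random() < pa:
            picks.append(next_a)
            next_a += 1
            rem_a -= 1
            prev = TargetClass.A
        else:
            picks.append(next_b)
            next_b += 1
            rem_b -= 1
            prev = TargetClass.B
    return Trial(stimulus=stim, selections=tuple(picks),
                 participant=participant, condition=condition,
                 trial_id=trial_id)


# ---------------------------------------------------------------------------
# fitting


def _step_arrays(dataset: Dataset):
    """Flatten a dataset into per-step design arrays for the logistic form.

    Returns (y, m, lr, pidx, participants): observed class (1 = a), previous
    class code, log count ratio, participant index. Forced steps (only one
    class left) contribute no information and are dropped; observing an
    exhausted class raises.
    """
    ys, ms, lrs, ps = [], [], [], []
    participants = sorted({t.participant for t in dataset})
    pmap = {p: i for i, p in enumerate(participants)}
    for t in dataset:
        n_a, n_b = t.stimulus.n_a, t.stimulus.n_b
        m = 0
        for cls in t.class_sequence:
            is_a = cls is TargetClass.A
            if (is_a and n_a == 0) or (not is_a and n_b == 0):
                raise ValueError(
                    f"trial {t.trial_id!r} selects an exhausted class")
            if n_a > 0 and n_b > 0:
                ys.append(1.0 if is_a else 0.0)
                ms.append(m)
                lrs.append(math.log(n_a / n_b))
                ps.append(pmap[t.participant])
            if is_a:
                n_a -= 1
                m = 1
            else:
                n_b -= 1
                m = -1
    rows = np.column_stack([ys, ms, lrs, ps])
    # many steps share a (y, m, count-ratio, participant) cell; aggregate
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    return (uniq[:, 0], uniq[:, 1], uniq[:, 2],
            uniq[:, 3].astype(int), counts.astype(float), participants)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray,
                      w: np.ndarray) -> np.ndarray:
    # weighted sum of y*log sigmoid(eta) + (1-y)*log sigmoid(-eta)
    return -(w * (np.logaddexp(0.0, -eta) * y
                  + np.logaddexp(0.0, eta) * (1.0 - y))).sum(axis=-1)


class BagForagingModel(BaseEstimator):
    """Bayesian bag foraging model with stick and class biases.

    Parameters
    ----------
    structure : {"single_trial", "by_condition", "multilevel"}
        ``single_trial`` fits the one-parameter stick-bias model (p_a fixed
        at 0.5). ``by_condition`` fits independent (b_a, b_s) per condition.
        ``multilevel`` adds per-participant random effects
        b = mu + tau * z (non-centered), independently per condition.
    prior_scale : float
        SD of the normal priors on b_s and b_a (logit scale).
    tau_scale : float
        Scale of the half-normal priors on the between-participant SDs.
    chains, iterations, walkers, warmup_steps
        MCMC settings (post-warmup draws per chain).
    random_state : int or None
        Seed for the sampler.

    Attributes
    ----------
    posterior_ : PosteriorDraws
        Draws for the logit-scale parameters plus probability-scale views
        (``p_s[...]``, ``p_a[...]``).
    diagnostics_ : DataFrame with split-R-hat / ESS per parameter.
    converged_ : bool, False when any parameter is flagged.
    """

    def __init__(self, structure: str = "by_condition", prior_scale: float = 1.0,
                 tau_scale: float = 1.0, chains: int = 4, iterations: int = 1000,
                 walkers: int | None = None, warmup_steps: int | None = None,
                 random_state: int | None = None):
        self.structure = structure
        self.prior_scale = prior_scale
        self.tau_scale = tau_scale
        self.chains = chains
        self.iterations = iterations
        self.walkers = walkers
        self.warmup_steps = warmup_steps
        self.random_state = random_state

    # -- internal ----------------------------------------------------------
    def _settings(self) -> MCMCSettings:
        return MCMCSettings(chains=self.chains, iterations=self.iterations,
                            walkers=self.walkers,
                            warmup_steps=self.warmup_steps)

    def _fit_condition(self, data: Dataset, seed: int):
        y, m, lr, pidx, w, participants = _step_arrays(data)
        sc2 = self.prior_scale ** 2

        if self.structure == "single_trial":
            def log_post(theta):
                b_s = theta[:, 0:1]
                eta = m[None, :] * b_s + lr[None, :]
                return _bernoulli_loglik(eta, y[None, :], w[None, :]) \
                    - 0.5 * (theta[:, 0] ** 2) / sc2
            draws = sample_ensemble(log_post, 1, seed=seed,
                                    settings=self._settings(), vectorized=True)
            return {"b_s": draws[:, :, 0]}, participants

        if self.structure == "by_condition":
            def log_post(theta):
                eta = theta[:, 0:1] + m[None, :] * theta[:, 1:2] + lr[None, :]
                return _bernoulli_loglik(eta, y[None, :], w[None, :]) \
                    - 0.5 * (theta ** 2).sum(axis=1) / sc2
            draws = sample_ensemble(log_post, 2, seed=seed,
                                    settings=self._settings(), vectorized=True)
            return {"b_a": draws[:, :, 0], "b_s": draws[:, :, 1]}, participants

        if self.structure == "multilevel":
            P = len(participants)
            ts2 = self.tau_scale ** 2

            def log_post(theta):
                mu = theta[:, 0:2]                       # (W, 2) mu_a, mu_s
                ltau = theta[:, 2:4]                     # log tau_a, log tau_s
                tau = np.exp(ltau)
                z_a = theta[:, 4:4 + P]
                z_s = theta[:, 4 + P:4 + 2 * P]
                b_a = mu[:, 0:1] + tau[:, 0:1] * z_a     # (W, P)
                b_s = mu[:, 1:2] + tau[:, 1:2] * z_s
                eta = b_a[:, pidx] + m[None, :] * b_s[:, pidx] + lr[None, :]
                lp = _bernoulli_loglik(eta, y[None, :], w[None, :])
                lp -= 0.5 * (mu ** 2).sum(axis=1) / sc2
                # half-normal prior on tau, sampled on the log scale
                lp += (-0.5 * tau ** 2 / ts2 + ltau).sum(axis=1)
                lp -= 0.5 * (z_a ** 2).sum(axis=1)
                lp -= 0.5 * (z_s ** 2).sum(axis=1)
                return lp

            ndim = 4 + 2 * P
            draws = sample_ensemble(log_post, ndim, seed=seed,
                                    settings=self._settings(), init_scale=0.3,
                                    vectorized=True)
            out = {"mu_a": draws[:, :, 0], "mu_s": draws[:, :, 1],
                   "tau_a": np.exp(draws[:, :, 2]),
                   "tau_s": np.exp(draws[:, :, 3])}
            for j, p in enumerate(participants):
                out[f"b_a[{p}]"] = draws[:, :, 0] \
                    + np.exp(draws[:, :, 2]) * draws[:, :, 4 + j]
                out[f"b_s[{p}]"] = draws[:, :, 1] \
                    + np.exp(draws[:, :, 3]) * draws[:, :, 4 + P + j]
            return out, participants

        raise ValueError(f"unknown structure {self.structure!r}")

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y=None):
        """Fit the model to a Dataset or a DataFrame in the CSV dialect."""
        data = X if isinstance(X, Dataset) else Dataset.from_frame(pd.DataFrame(X))
        if len(data) == 0:
            raise ValueError("empty dataset")
        self.conditions_ = data.conditions
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            len(self.conditions_))
        raw: dict[str, np.ndarray] = {}
        transforms: dict[str, tuple] = {}
        multi = len(self.conditions_) > 1
        for cond, seed in zip(self.conditions_, seeds):
            cdraws, participants = self._fit_condition(
                data.by_condition(cond), int(seed) % (2**31 - 1))
            suffix = f"[{cond}]" if multi else ""
            for name, arr in cdraws.items():
                raw[name + suffix] = arr
        self.participants_ = data.participants
        for name in list(raw):
            if name.startswith(("b_", "mu_")):
                pname = "p" + name[name.index("_"):]
                transforms[pname] = (name, expit)
        self.posterior_ = PosteriorDraws(raw, transforms)
        self.diagnostics_ = self.posterior_.diagnostics()
        self.converged_ = not bool(self.diagnostics_["flagged"].any())
        self.summary_ = self.posterior_.summary()
        return self

    def score(self, X, y=None) -> float:
        """Mean per-trial log likelihood at the posterior-mean biases.

        Only defined for the single-condition, non-hierarchical structures.
        """
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "posterior_")
        data = X if isinstance(X, Dataset) else Dataset.from_frame(pd.DataFrame(X))
        if self.structure == "single_trial":
            params = BagParams.from_logits(b_s=self.posterior_.mean("b_s"))
        elif self.structure == "by_condition" and len(self.conditions_) == 1:
            params = BagParams.from_logits(b_s=self.posterior_.mean("b_s"),
                                           b_a=self.posterior_.mean("b_a"))
        else:
            raise ValueError("score() needs a single-condition fit")
        return dataset_loglik(data, params) / len(data)


def fit_bag(dataset: Dataset, structure: str = "by_condition",
            mcmc: MCMCSettings | None = None,
            seed: int | None = None) -> PosteriorDraws:
    """Fit the bag model and return the posterior draws."""
    kw = {}
    if mcmc is not None:
        kw = dict(chains=mcmc.chains, iterations=mcmc.iterations,
                  walkers=mcmc.walkers, warmup_steps=mcmc.warmup_steps)
    model = BagForagingModel(structure=structure, random_state=seed, **kw)
    return model.fit(dataset).posterior_
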