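"""Spatial foraging model: categorical selection over remaining targets.

Each remaining target ``i`` gets an unnormalized weight

    w(i) = g(b_a t_i + b_s m(t_i, t_prev)) * exp(-sigma_d d) * exp(-sigma_theta theta)

where ``g`` is the inverse logit, ``t_i`` is the signed class code (+1 = a,
-1 = b), ``m`` is +1 when candidate and previous class match and -1
otherwise, ``d`` is the distance (in stimulus-width units) from the previous
selection, and ``theta`` in [0, 1] is the angular deviation from the current
direction of travel (0 = straight ahead, 1 = full reversal). Already-selected
targets have weight exactly 0. On the first selection only the class term
applies; on the second the direction term is dropped (no travel direction
exists yet).

``sigma_d`` (proximity tuning, >= 0 by default) and ``sigma_theta``
(direction/momentum tuning; negative values favour doubling back) equal to 0
disable the respective weight, which makes the class-marginal of this model
identical to the bag model with the same ``b_a, b_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .data import Dataset, Stimulus, TargetClass, Trial
from .inference import MCMCSettings, PosteriorDraws, sample_ensemble

__all__ = [
    "SpatialParams", "SelectionState", "angular_deviation", "proximity_weight",
    "selection_distribution", "simulate_spatial_trial", "spatial_trial_loglik",
    "SpatialForagingModel", "fit_spatial",
]


@dataclass(frozen=True)
class SpatialParams:
    """Class, stick, proximity and direction biases of the spatial model."""

    b_a: float = 0.0
    b_s: float = 0.0
    sigma_d: float = 0.0
    sigma_theta: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.b_a, self.b_s, self.sigma_d, self.sigma_theta])


@dataclass(frozen=True)
class SelectionState:
    """What the chooser knows mid-trial: the pool and the recent path."""

    stimulus: Stimulus
    remaining: tuple[int, ...]
    prev: int | None = None          # previously selected target id
    prev2: int | None = None         # selection before that

    def __post_init__(self):
        if self.prev is not None and self.prev in self.remaining:
            raise ValueError("previous selection still in remaining set")


def angular_deviation(prev2, prev1, candidate) -> float:
    """Angular deviation of the step prev1 -> candidate from prev2 -> prev1.

    Returns theta in [0, 1]: 0 = continuing straight ahead, 0.5 = a 90-degree
    turn, 1 = doubling back. Raises when the incoming travel vector has zero
    length (direction undefined).
    """
    p2, p1, c = (np.asarray(p, dtype=float) for p in (prev2, prev1, candidate))
    v_in = p1 - p2
    if np.allclose(v_in, 0.0):
        raise ValueError("zero-length travel vector: direction undefined")
    phi_in = math.atan2(v_in[1], v_in[0])
    v_out = c - p1
    phi_out = math.atan2(v_out[1], v_out[0])
    two_pi = 2.0 * math.pi
    diff = min((phi_out - phi_in) % two_pi, (phi_in - phi_out) % two_pi)
    return diff / math.pi


def proximity_weight(d, sigma_d: float):
    """Exponential proximity weight exp(-sigma_d * d); 1 at distance 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    out = np.exp(-sigma_d * d)
    return float(out) if out.ndim == 0 else out


def _candidate_logweights(state: SelectionState,
                          params: SpatialParams) -> np.ndarray:
    """Log weights for the remaining targets, in ``state.remaining`` order."""
    stim = state.stimulus
    by_id = stim._by_id
    codes = np.array([by_id[i].cls.code for i in state.remaining], dtype=float)
    eta = params.b_a * codes
    if state.prev is not None:
        prev_t = by_id[state.prev]
        eta = eta + params.b_s * codes * prev_t.cls.code
    logw = -np.logaddexp(0.0, -eta)        # log inverse-logit
    if state.prev is not None and stim.is_spatial:
        ppos = np.asarray(prev_t.pos, dtype=float)
        cand = np.array([by_id[i].pos for i in state.remaining], dtype=float)
        d = np.linalg.norm(cand - ppos, axis=1)
        logw = logw - params.sigma_d * d
        if state.prev2 is not None:
            p2pos = np.asarray(by_id[state.prev2].pos, dtype=float)
            th = np.array([angular_deviation(p2pos, ppos, c) for c in cand])
            logw = logw - params.sigma_theta * th
    return logw


def selection_distribution(state: SelectionState,
                           params: SpatialParams) -> dict[int, float]:
    """Categorical selection probabilities over the remaining targets."""
    if not state.remaining:
        raise ValueError("no remaining targets")
    logw = _candidate_logweights(state, params)
    logw = logw - logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return dict(zip(state.remaining, w.tolist()))


def simulate_spatial_trial(stimulus: Stimulus, params: SpatialParams,
                           length: int | None = None, seed=None, *,
                           participant: str = "p1", condition: str = "c1",
                           trial_id: str = "t1") -> Trial:
    """Draw one trial by sequential categorical sampling; seed-reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if length is None:
        length = stimulus.n_T
    if length > stimulus.n_T:
        raise ValueError("trial length exceeds number of targets")
    remaining = [t.id for t in stimulus.targets]
    prev = prev2 = None
    picks: list[int] = []
    for _ in range(length):
        state = SelectionState(stimulus, tuple(remaining), prev, prev2)
        logw = _candidate_logweights(state, params)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        choice = remaining[rng.choice(len(remaining), p=w)]
        picks.append(choice)
        remaining.remove(choice)
        prev2, prev = prev, choice
    return Trial(stimulus=stimulus, selections=tuple(picks),
                 participant=participant, condition=condition,
                 trial_id=trial_id)


# ---------------------------------------------------------------------------
# vectorized likelihood

class _TrialMatrices:
    """Per-trial precomputed design matrices for the categorical likelihood.

    All matrices have shape (L, N): selection step x target. Disabled factors
    (distance on the first step, direction on the first two) are encoded as
    zeros, i.e. multiplicative weight 1.
    """

    def __init__(self, trial: Trial):
        stim = trial.stimulus
        ids = [t.id for t in stim.targets]
        idx = {tid: j for j, tid in enumerate(ids)}
        codes = stim.codes()
        sel = np.array([idx[i] for i in trial.selections], dtype=int)
        L, N = len(sel), stim.n_T
        self.chosen = sel
        self.codes = codes
        self.stick = np.zeros((L, N))
        self.dist = np.zeros((L, N))
        self.theta = np.zeros((L, N))
        self.avail = np.ones((L, N), dtype=bool)
        spatial = stim.is_spatial
        pos = stim.positions() if spatial else None
        for k in range(L):
            if k > 0:
                self.avail[k] = self.avail[k - 1].copy()
                self.avail[k, sel[k - 1]] = False
                prev = sel[k - 1]
                self.stick[k] = codes * codes[prev]
                if spatial:
                    self.dist[k] = np.linalg.norm(pos - pos[prev], axis=1)
                    if k > 1:
                        v_in = pos[prev] - pos[sel[k - 2]]
                        phi_in = math.atan2(v_in[1], v_in[0])
                        v_out = pos - pos[prev]
                        phi_out = np.arctan2(v_out[:, 1], v_out[:, 0])
                        diff = np.minimum((phi_out - phi_in) % (2 * math.pi),
                                          (phi_in - phi_out) % (2 * math.pi))
                        self.theta[k] = diff / math.pi

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        """Log likelihood for parameter rows theta (W, 4) -> (W,)."""
        codes = np.tile(self.codes, (len(self.chosen), 1))
        return _stacked_loglik(theta, _combo_index(codes, self.stick),
                               self.dist, self.theta, self.avail, self.chosen)


# the class/stick logit takes only 6 distinct values per parameter vector:
# (code, stick) in {-1,+1} x {-1,0,+1}; a lookup table avoids a softplus
# over the full (steps x targets) array
_CV6 = np.array([-1.0, 1.0] * 3)
_SV6 = np.repeat([-1.0, 0.0, 1.0], 2)


def _combo_index(codes: np.ndarray, stick: np.ndarray) -> np.ndarray:
    return ((codes > 0).astype(np.intp)
            + (stick.astype(np.intp) + 1) * 2)


def _stacked_loglik(theta, combo, dist, th, avail, chosen):
    """Categorical log likelihood over stacked (steps, targets) matrices."""
    s_d = theta[:, 2, None, None]
    s_t = theta[:, 3, None, None]
    eta6 = theta[:, 0:1] * _CV6[None, :] + theta[:, 1:2] * _SV6[None, :]
    table = -np.logaddexp(0.0, -eta6)            # (W, 6) log inverse-logit
    logw = table[:, combo]                       # (W, steps, targets)
    logw -= s_d * dist[None, :, :]
    logw -= s_t * th[None, :, :]
    logw = np.where(avail[None, :, :], logw, -np.inf)
    m = logw.max(axis=2, keepdims=True)
    lse = m[:, :, 0] + np.log(np.exp(logw - m).sum(axis=2))
    picked = logw[:, np.arange(len(chosen)), chosen]
    return (picked - lse).sum(axis=1)


class _StackedMatrices:
    """Trial matrices concatenated along the step axis for fast fitting.

    Requires all trials to share the same target count; falls back to a
    per-trial list otherwise.
    """

    def __init__(self, trials):
        mats = [_TrialMatrices(t) for t in trials]
        sizes = {m.codes.size for m in mats}
        if len(sizes) == 1:
            self._stacked = True
            codes = np.concatenate(
                [np.tile(m.codes, (len(m.chosen), 1)) for m in mats])
            stick = np.concatenate([m.stick for m in mats])
            self.combo = _combo_index(codes, stick)
            self.dist = np.concatenate([m.dist for m in mats])
            self.theta = np.concatenate([m.theta for m in mats])
            self.avail = np.concatenate([m.avail for m in mats])
            self.chosen = np.concatenate([m.chosen for m in mats])
        else:
            self._stacked = False
            self._mats = mats

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        if self._stacked:
            return _stacked_loglik(theta, self.combo, self.dist,
                                   self.theta, self.avail, self.chosen)
        return sum(m.loglik(theta) for m in self._mats)


def spatial_trial_loglik(trial: Trial, params: SpatialParams) -> float:
    """Log probability of a trial's full selection order under the model."""
    if not trial.stimulus.is_spatial:
        # degenerate to class/stick terms only; matrices handle it (all
        # distance and direction entries stay 0)
        pass
    mats = _TrialMatrices(trial)
    return float(mats.loglik(params.as_array()[None, :])[0])


class SpatialForagingModel(BaseEstimator):
    """Bayesian spatial foraging model (class, stick, proximity, momentum).

    Parameters
    ----------
    structure : {"pooled", "multilevel"}
        ``pooled`` fits one parameter set per condition (participants
        pooled). ``multilevel`` adds per-participant random effects for all
        four parameters with an estimated correlation structure
        (``diagonal_effects=True`` switches to independent effects).
    prior_scale : SD of the N(0, .) priors on b_a and b_s.
    sigma_d_scale : scale of the (half-)normal prior on sigma_d.
    positive_sigma_d : constrain sigma_d >= 0 (default); set False to allow
        a preference for far targets.
    sigma_theta_scale : SD of the normal prior on sigma_theta (unconstrained:
        fitted direction biases can be negative, i.e. doubling back).
    tau_scale : scale of the half-normal priors on random-effect SDs.

    Attributes
    ----------
    posterior_ : PosteriorDraws with logit-scale biases, tuning parameters,
        and probability-scale views of b_a, b_s.
    """

    _PNAMES = ("b_a", "b_s", "sigma_d", "sigma_theta")

    def __init__(self, structure: str = "pooled", prior_scale: float = 1.0,
                 sigma_d_scale: float = 20.0, sigma_theta_scale: float = 5.0,
                 positive_sigma_d: bool = True, tau_scale: float = 1.0,
                 diagonal_effects: bool = False, chains: int = 4,
                 iterations: int = 1000, walkers: int | None = None,
                 warmup_steps: int | None = None,
                 random_state: int | None = None):
        self.structure = structure
        self.prior_scale = prior_scale
        self.sigma_d_scale = sigma_d_scale
        self.sigma_theta_scale = sigma_theta_scale
        self.positive_sigma_d = positive_sigma_d
        self.tau_scale = tau_scale
        self.diagonal_effects = diagonal_effects
        self.chains = chains
        self.iterations = iterations
        self.walkers = walkers
        self.warmup_steps = warmup_steps
        self.random_state = random_state

    def _settings(self) -> MCMCSettings:
        return MCMCSettings(chains=self.chains, iterations=self.iterations,
                            walkers=self.walkers,
                            warmup_steps=self.warmup_steps)

    def _log_prior_pooled(self, theta: np.ndarray) -> np.ndarray:
        lp = -0.5 * (theta[:, 0] ** 2 + theta[:, 1] ** 2) / self.prior_scale ** 2
        lp = lp - 0.5 * theta[:, 2] ** 2 / self.sigma_d_scale ** 2
        lp = lp - 0.5 * theta[:, 3] ** 2 / self.sigma_theta_scale ** 2
        if self.positive_sigma_d:
            lp = np.where(theta[:, 2] < 0, -np.inf, lp)
        return lp

    def _fit_condition(self, data: Dataset, seed: int):
        participants = data.participants

        if self.structure == "pooled":
            stacked = _StackedMatrices(list(data))

            def log_post(theta):
                lp = self._log_prior_pooled(theta)
                ok = np.isfinite(lp)
                if ok.any():
                    lp[ok] += stacked.loglik(theta[ok])
                return lp
            draws = sample_ensemble(
                log_post, 4, seed=seed, settings=self._settings(),
                init=np.array([0.0, 0.0, 1.0, 0.0]), init_scale=0.3,
                vectorized=True)
            out = {n: draws[:, :, j] for j, n in enumerate(self._PNAMES)}
            return out, participants

        if self.structure == "multilevel":
            return self._fit_multilevel(data, participants, seed)
        raise ValueError(f"unknown structure {self.structure!r}")

    def _fit_multilevel(self, data, participants, seed):
        P = len(participants)
        pmap = {p: i for i, p in enumerate(participants)}
        part_mats = {
            pi: _StackedMatrices([t for t in data if pmap[t.participant] == pi])
            for pi in range(P)}
        K = 4
        n_corr = 0 if self.diagonal_effects else K * (K - 1) // 2
        ndim = 2 * K + n_corr + K * P
        tril = np.tril_indices(K, -1)
        ts2 = self.tau_scale ** 2

        def unpack(theta):
            W = theta.shape[0]
            mu = theta[:, :K]
            ltau = theta[:, K:2 * K]
            tau = np.exp(ltau)
            z = theta[:, 2 * K + n_corr:].reshape(W, P, K)
            if self.diagonal_effects:
                Lc = np.broadcast_to(np.eye(K), (W, K, K))
            else:
                V = np.zeros((W, K, K))
                V[:, np.arange(K), np.arange(K)] = 1.0
                V[:, tril[0], tril[1]] = theta[:, 2 * K:2 * K + n_corr]
                # row-normalized Cholesky factor of a correlation matrix
                Lc = V / np.linalg.norm(V, axis=2, keepdims=True)
            eff = np.einsum("wij,wpj->wpi", Lc, z)
            b = mu[:, None, :] + tau[:, None, :] * eff    # (W, P, K)
            return mu, ltau, tau, z, b

        def log_post(theta):
            mu, ltau, tau, z, b = unpack(theta)
            lp = -0.5 * (mu[:, 0] ** 2 + mu[:, 1] ** 2) / self.prior_scale ** 2
            lp = lp - 0.5 * mu[:, 2] ** 2 / self.sigma_d_scale ** 2
            lp = lp - 0.5 * mu[:, 3] ** 2 / self.sigma_theta_scale ** 2
            lp = lp + (-0.5 * tau ** 2 / ts2 + ltau).sum(axis=1)
            lp = lp - 0.5 * (z ** 2).sum(axis=(1, 2))
            if n_corr:
                lp = lp - 0.5 * (theta[:, 2 * K:2 * K + n_corr] ** 2).sum(axis=1)
            if self.positive_sigma_d:
                lp = np.where((b[:, :, 2] < 0).any(axis=1), -np.inf, lp)
            ok = np.isfinite(lp)
            if ok.any():
                bok = b[ok]
                ll = np.zeros(bok.shape[0])
                for pi, m in part_mats.items():
                    ll += m.loglik(bok[:, pi, :])
                lp[ok] += ll
            return lp

        init = np.zeros(ndim)
        init[2] = 1.0                      # mu for sigma_d starts positive
        init[K:2 * K] = math.log(0.3)      # modest random-effect SDs
        draws = sample_ensemble(log_post, ndim, seed=seed,
                                settings=self._settings(), init=init,
                                init_scale=0.1, vectorized=True)
        flat = draws.reshape(-1, ndim)
        _, _, _, _, b = unpack(flat)
        C = draws.shape[0]
        b = b.reshape(C, -1, P, K)
        out = {}
        for j, n in enumerate(self._PNAMES):
            out[f"mu_{n}"] = draws[:, :, j]
            out[f"tau_{n}"] = np.exp(draws[:, :, K + j])
            for p in participants:
                out[f"{n}[{p}]"] = b[:, :, pmap[p], j]
        return out, participants

    def fit(self, X, y=None):
        """Fit to a spatial Dataset (or DataFrame in the CSV dialect)."""
        data = X if isinstance(X, Dataset) else Dataset.from_frame(pd.DataFrame(X))
        if len(data) == 0:
            raise ValueError("empty dataset")
        if not data.is_spatial:
            raise ValueError("spatial model requires target positions")
        self.conditions_ = data.conditions
        self.participants_ = data.participants
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            len(self.conditions_))
        multi = len(self.conditions_) > 1
        raw: dict[str, np.ndarray] = {}
        transforms: dict[str, tuple] = {}
        for cond, seed in zip(self.conditions_, seeds):
            cdraws, _ = self._fit_condition(
                data.by_condition(cond), int(seed) % (2 ** 31 - 1))
            suffix = f"[{cond}]" if multi else ""
            for name, arr in cdraws.items():
                raw[name + suffix] = arr
        for name in list(raw):
            if name.startswith(("b_a", "b_s")):
                transforms["p" + name[1:]] = (name, expit)      # p_a[...]
            elif name.startswith(("mu_b_a", "mu_b_s")):
                transforms["mu_p" + name[4:]] = (name, expit)   # mu_p_a[...]
        self.posterior_ = PosteriorDraws(raw, transforms)
        self.diagnostics_ = self.posterior_.diagnostics()
        self.converged_ = not bool(self.diagnostics_["flagged"].any())
        self.summary_ = self.posterior_.summary()
        return self


def fit_spatial(dataset: Dataset, structure: str = "pooled",
                mcmc: MCMCSettings | None = None,
                seed: int | None = None) -> PosteriorDraws:
    """Fit the spatial model and return the posterior draws."""
    kw = {}
    if mcmc is not None:
        kw = dict(chains=mcmc.chains, iterations=mcmc.iterations,
                  walkers=mcmc.walkers, warmup_steps=mcmc.warmup_steps)
    model = SpatialForagingModel(structure=structure, random_state=seed, **kw)
    return model.fit(dataset).posterior_
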