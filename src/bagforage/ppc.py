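"""Posterior predictive checks on run statistics and step distances.

Given a fitted posterior, simulate replicate datasets on the observed
stimulus layouts (one per posterior draw) and compare, per trial, the run
statistics — and for spatial data the mean inter-target distance by
selection index — between observation and predictive ensemble. Intervals
are 89% HPDIs of the predictive distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bag import BagParams, simulate_bag_trial
from .data import Dataset, Stimulus, Trial, intertarget_distances, run_summary
from .inference import Interval, PosteriorDraws, hpdi
from .spatial import SpatialParams, simulate_spatial_trial

__all__ = ["posterior_predict", "ppc_report", "PpcReport"]

PREDICTIVE_MASS = 0.89


def _params_from_draw(post: PosteriorDraws, i: int, spatial: bool,
                      condition: str | None):
    suffix = f"[{condition}]" if condition else ""

    def d(name, default=None):
        try:
            return float(post.get(name + suffix)[i])
        except KeyError:
            if default is None:
                raise
            return default

    if spatial:
        return SpatialParams(b_a=d("b_a"), b_s=d("b_s"),
                             sigma_d=d("sigma_d"),
                             sigma_theta=d("sigma_theta"))
    return BagParams.from_logits(b_s=d("b_s"), b_a=d("b_a", 0.0))


def posterior_predict(fit, stimuli, n_draws: int = 100, seed=None, *,
                      condition: str | None = None,
                      trial_lengths=None) -> list[Dataset]:
    """Simulate ``n_draws`` replicate datasets from a fitted posterior.

    ``fit`` is a :class:`PosteriorDraws` (or a fitted model exposing
    ``posterior_``); ``stimuli`` a list of :class:`Stimulus` — the layouts
    on which to forage, typically those of the observed trials. Each
    replicate uses one parameter draw for all its trials. If ``n_draws``
    exceeds the available posterior draws, draws are re-used (sampled with
    replacement, with a warning). ``condition`` selects the parameter set
    of a multi-condition fit.
    """
    post: PosteriorDraws = getattr(fit, "posterior_", fit)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spatial = any(p.split("[")[0] == "sigma_d" for p in post.parameters)
    total = post.n_chains * post.n_iterations
    if n_draws > total:
        warnings.warn(f"requested {n_draws} predictive draws from {total} "
                      "posterior draws; sampling with replacement")
        idx = rng.choice(total, size=n_draws, replace=True)
    else:
        idx = rng.choice(total, size=n_draws, replace=False)
    if trial_lengths is None:
        trial_lengths = [None] * len(stimuli)
    datasets = []
    for i in idx:
        params = _params_from_draw(post, int(i), spatial, condition)
        trials = []
        for j, (stim, length) in enumerate(zip(stimuli, trial_lengths)):
            tid = f"t{j + 1}"
            if stim.is_spatial:
                # a bag fit predicting onto spatial layouts uses the
                # equivalent spatial model with both spatial weights off
                # (same-class targets are interchangeable under it)
                sp = params if isinstance(params, SpatialParams) else \
                    SpatialParams(b_a=params.b_a, b_s=params.b_s)
                trials.append(simulate_spatial_trial(
                    stim, sp, length=length, seed=rng, trial_id=tid))
            else:
                if isinstance(params, SpatialParams):
                    raise ValueError(
                        "spatial fit cannot predict onto stimuli "
                        "without positions")
                trials.append(simulate_bag_trial(
                    stim.n_a, stim.n_b, params, length=length, seed=rng,
                    trial_id=tid))
        datasets.append(Dataset(trials))
    return datasets


@dataclass
class PpcReport:
    """Observed-vs-predicted summaries.

    ``run_stats`` has one row per trial: observed n_runs / max_run with
    predictive means and 89% interval bounds. ``distance_profile`` (spatial
    only, else None) has one row per selection-step index with the observed
    mean step distance across trials and the predictive mean and band.
    """

    run_stats: pd.DataFrame
    distance_profile: pd.DataFrame | None

    def run_stat_coverage(self) -> float:
        """Fraction of (trial, statistic) pairs inside the predictive band."""
        rs = self.run_stats
        hits = 0
        for stat in ("n_runs", "max_run"):
            hits += ((rs[f"obs_{stat}"] >= rs[f"pred_{stat}_lo"])
                     & (rs[f"obs_{stat}"] <= rs[f"pred_{stat}_hi"])).sum()
        return float(hits) / (2 * len(rs))

    def distance_mismatch_fraction(self) -> float | None:
        """Fraction of selection steps whose observed mean distance falls
        outside the predictive band; None without a distance profile."""
        dp = self.distance_profile
        if dp is None:
            return None
        eps = 1e-9 * (1.0 + dp["obs_mean_distance"].abs())
        out = ((dp["obs_mean_distance"] < dp["pred_lo"] - eps)
               | (dp["obs_mean_distance"] > dp["pred_hi"] + eps)).mean()
        return float(out)

    def to_json_dict(self) -> dict:
        out = {"run_stats": self.run_stats.to_dict(orient="records")}
        if self.distance_profile is not None:
            out["distance_profile"] = self.distance_profile.to_dict(
                orient="records")
        return out


def _band(x, mass: float = PREDICTIVE_MASS) -> Interval:
    # tiny ensembles cannot support an HPDI; fall back to the sample range
    try:
        return hpdi(x, mass)
    except ValueError:
        return Interval(mass=mass, lower=float(np.min(x)),
                        upper=float(np.max(x)))


def _trial_stats(dataset: Dataset) -> np.ndarray:
    return np.array([[run_summary(t).n_runs, run_summary(t).max_run]
                     for t in dataset])


def ppc_report(observed: Dataset, predicted: list[Dataset]) -> PpcReport:
    """Compare run statistics (and distances) against a predictive ensemble.

    Predicted datasets must have the same trial structure as the observed
    one. Distance profiles are aggregated across trials by selection index
    and truncated at the shortest common trial length.
    """
    if len(predicted) < 2:
        raise ValueError("need >= 2 predictive datasets for intervals")
    n_trials = len(observed)
    for d in predicted:
        if len(d) != n_trials:
            raise ValueError("predicted dataset trial count mismatch")
    obs = _trial_stats(observed)
    pred = np.stack([_trial_stats(d) for d in predicted])  # (R, T, 2)
    rows = []
    for t in range(n_trials):
        row = {"trial": observed.trials[t].trial_id,
               "obs_n_runs": int(obs[t, 0]), "obs_max_run": int(obs[t, 1])}
        for j, name in enumerate(("n_runs", "max_run")):
            iv = _band(pred[:, t, j])
            row[f"pred_{name}_mean"] = float(pred[:, t, j].mean())
            row[f"pred_{name}_lo"] = iv.lower
            row[f"pred_{name}_hi"] = iv.upper
        rows.append(row)
    run_stats = pd.DataFrame(rows)

    profile = None
    if observed.is_spatial:
        min_len = min(len(t) for t in observed)
        obs_d = np.stack([intertarget_distances(t)[: min_len - 1]
                          for t in observed])
        pred_d = np.stack([
            np.stack([intertarget_distances(t)[: min_len - 1] for t in d])
            for d in predicted])                     # (R, T, L-1)
        pred_mean = pred_d.mean(axis=1)              # mean over trials
        prows = []
        for k in range(min_len - 1):
            iv = _band(pred_mean[:, k])
            prows.append({
                "step": k + 1,
                "obs_mean_distance": float(obs_d[:, k].mean()),
                "pred_mean_distance": float(pred_mean[:, k].mean()),
                "pred_lo": iv.lower, "pred_hi": iv.upper,
            })
        profile = pd.DataFrame(prows)
    return PpcReport(run_stats=run_stats, distance_profile=profile)
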