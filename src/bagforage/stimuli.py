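"""Synthetic stimulus layouts and full experiment generators.

Layouts place two classes of targets in a unit-width frame:

* ``uniform`` — independent uniform positions;
* ``grid`` — jittered square lattice, classes assigned at random;
* ``patchy`` — per-class cluster centers with Gaussian scatter, emulating
  clumped environments where same-class targets sit near each other.

Experiment designs pair per-condition generating parameters (bag or
spatial) with a trial count, target composition and optionally a
multi-participant structure whose per-participant biases are drawn on the
logit scale around the population values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .bag import BagParams, simulate_bag_trial
from .data import Dataset, Stimulus, TargetClass
from .spatial import SpatialParams, simulate_spatial_trial

__all__ = ["StimulusSpec", "ExperimentDesign", "make_stimulus",
           "generate_experiment"]

#: minimum center-to-center separation when resolving collisions
_MIN_SEP = 1e-3
_MAX_RETRIES = 200


@dataclass(frozen=True)
class StimulusSpec:
    """Recipe for one stimulus layout.

    ``spread`` is the per-axis SD of the Gaussian scatter around patch
    centers, in stimulus-width units. Patch centers are kept away from the
    frame edge by one spread.
    """

    layout: str = "uniform"            # uniform | grid | patchy
    n_a: int = 20
    n_b: int = 20
    clusters_per_class: int = 2
    spread: float = 0.08
    height: float = 1.0

    def __post_init__(self):
        if self.layout not in ("uniform", "grid", "patchy"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_a < 0 or self.n_b < 0:
            raise ValueError("counts must be nonnegative")
        if self.layout == "patchy" and self.spread <= 0:
            raise ValueError("patchy layout needs spread > 0")


def _too_close(pos: list, cand: np.ndarray) -> bool:
    return any(np.hypot(p[0] - cand[0], p[1] - cand[1]) < _MIN_SEP for p in pos)


def make_stimulus(spec: StimulusSpec, seed=None) -> Stimulus:
    """Generate a spatial stimulus from a spec; reproducible by seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_a + spec.n_b
    classes = [TargetClass.A] * spec.n_a + [TargetClass.B] * spec.n_b

    if spec.layout == "uniform":
        positions = _scatter_uniform(rng, n, spec.height)
    elif spec.layout == "grid":
        positions = _grid_positions(rng, n, spec.height)
        order = rng.permutation(n)
        classes = [classes[i] for i in order]
    else:
        positions = _patchy_positions(rng, spec)
    return Stimulus.from_classes(classes, positions, height=spec.height)


def _scatter_uniform(rng, n, height):
    positions: list[tuple[float, float]] = []
    for _ in range(n):
        for _ in range(_MAX_RETRIES):
            cand = rng.uniform([0, 0], [1, height])
            if not _too_close(positions, cand):
                break
        else:
            raise RuntimeError("could not place targets without collisions")
        positions.append(tuple(cand))
    return positions


def _grid_positions(rng, n, height):
    side = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(side) + 0.5) / side
    ys = (np.arange(side) + 0.5) / side * height
    grid = [(x, y) for y in ys for x in xs]
    idx = rng.choice(len(grid), size=n, replace=False)
    jitter = 0.1 / side
    out = []
    for i in idx:
        gx, gy = grid[i]
        out.append((float(np.clip(gx + rng.uniform(-jitter, jitter), 0, 1)),
                    float(np.clip(gy + rng.uniform(-jitter, jitter), 0, height))))
    return out


def _patchy_positions(rng, spec: StimulusSpec):
    margin = min(spec.spread, 0.45)
    positions: list[tuple[float, float]] = []
    for n_cls in (spec.n_a, spec.n_b):
        centers = rng.uniform([margin, margin],
                              [1 - margin, spec.height - margin],
                              size=(spec.clusters_per_class, 2))
        sizes = np.full(spec.clusters_per_class,
                        n_cls // spec.clusters_per_class)
        sizes[: n_cls % spec.clusters_per_class] += 1
        for center, k in zip(centers, sizes):
            for _ in range(int(k)):
                for _ in range(_MAX_RETRIES):
                    cand = center + spec.spread * rng.standard_normal(2)
                    inside = (0 <= cand[0] <= 1
                              and 0 <= cand[1] <= spec.height)
                    if inside and not _too_close(positions, cand):
                        break
                else:
                    raise RuntimeError(
                        "could not place targets without collisions")
                positions.append(tuple(cand))
    return positions


@dataclass(frozen=True)
class ExperimentDesign:
    """A multi-condition simulated experiment.

    ``conditions`` maps condition names to generating parameters
    (:class:`BagParams` or :class:`SpatialParams`). With ``participants``
    set, each participant's logit-scale biases are drawn from normal
    distributions centered on the condition values with SD
    ``participant_sd``, and each participant contributes
    ``trials_per_condition`` trials.
    """

    conditions: dict
    trials_per_condition: int = 50
    n_a: int = 20
    n_b: int = 20
    trial_length: int | None = None
    participants: int | None = None
    participant_sd: float = 0.3
    stimulus: StimulusSpec | None = None   # required for SpatialParams

    def __post_init__(self):
        if self.trials_per_condition < 1 or self.n_a + self.n_b < 1:
            raise ValueError("need at least one trial and one target")


def _perturb(params, sd: float, rng) -> "BagParams | SpatialParams":
    if isinstance(params, BagParams):
        return BagParams.from_logits(
            b_s=params.b_s + sd * rng.standard_normal(),
            b_a=params.b_a + sd * rng.standard_normal())
    return replace(params,
                   b_a=params.b_a + sd * rng.standard_normal(),
                   b_s=params.b_s + sd * rng.standard_normal())


def generate_experiment(design: ExperimentDesign, seed=None) -> Dataset:
    """Simulate the full dataset a design describes; reproducible by seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = []
    participants = ([f"p{i + 1}" for i in range(design.participants)]
                    if design.participants else ["p1"])
    for cond, params in design.conditions.items():
        spatial = isinstance(params, SpatialParams)
        if spatial and design.stimulus is None:
            raise ValueError("spatial conditions need a stimulus spec")
        for part in participants:
            pparams = (params if design.participants is None
                       else _perturb(params, design.participant_sd, rng))
            for j in range(design.trials_per_condition):
                tid = f"t{j + 1}"
                if spatial:
                    spec = replace(design.stimulus,
                                   n_a=design.n_a, n_b=design.n_b)
                    stim = make_stimulus(spec, seed=rng)
                    trials.append(simulate_spatial_trial(
                        stim, pparams, length=design.trial_length, seed=rng,
                        participant=part, condition=cond, trial_id=tid))
                else:
                    trials.append(simulate_bag_trial(
                        design.n_a, design.n_b, pparams,
                        length=design.trial_length, seed=rng,
                        participant=part, condition=cond, trial_id=tid))
    return Dataset(trials)
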