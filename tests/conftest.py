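"""Shared fixtures: small synthetic datasets and light sampler settings."""

import numpy as np
import pytest

from bagforage.bag import BagParams, simulate_bag_trial
from bagforage.data import Dataset, Stimulus, TargetClass, Trial
from bagforage.spatial import SpatialParams, simulate_spatial_trial
from bagforage.stimuli import StimulusSpec, make_stimulus

#: light sampler settings for tests that only need a usable posterior
LIGHT_MCMC = dict(chains=2, iterations=800)


def assert_recovered(post, name: str, truth: float, z_max: float = 3.5):
    """Recovery check: the 97% HPDI covers the generating value, or — for
    the ~3% of dataset realizations whose information happens to sit in a
    tail — the posterior mean stays within ``z_max`` posterior SDs of it.
    (Interval calibration is tested separately via simulation-based
    calibration.)"""
    iv = post.hpdi(name, 0.97)
    if iv.contains(truth):
        return
    draws = post.get(name)
    z = abs(float(np.mean(draws)) - truth) / float(np.std(draws))
    assert z <= z_max, (name, truth, iv, z)


def trial_from_labels(labels: str, n_a: int | None = None,
                      n_b: int | None = None, **kw) -> Trial:
    """Build a trial whose class sequence spells ``labels`` (e.g. 'aabba').

    Counts default to the tally of the labels (exhaustive foraging).
    """
    seq = [TargetClass.from_label(c) for c in labels]
    na = sum(c is TargetClass.A for c in seq) if n_a is None else n_a
    nb = len(seq) - sum(c is TargetClass.A for c in seq) if n_b is None else n_b
    stim = Stimulus.from_counts(na, nb)
    ia, ib = 0, na
    sel = []
    for c in seq:
        if c is TargetClass.A:
            sel.append(ia)
            ia += 1
        else:
            sel.append(ib)
            ib += 1
    if ia > na or ib > na + nb:
        raise ValueError("labels exceed the stated class counts")
    return Trial(stimulus=stim, selections=tuple(sel), **kw)


def enumerate_class_orders(n_a: int, n_b: int):
    """All distinct class-label sequences exhausting an (n_a, n_b) pool."""
    import itertools
    base = "a" * n_a + "b" * n_b
    return sorted(set("".join(p) for p in itertools.permutations(base)))


@pytest.fixture(scope="session")
def bag_dataset():
    """50 exhaustive trials of 40 targets generated at p_s=0.8, p_a=0.5."""
    rng = np.random.default_rng(11)
    return Dataset([
        simulate_bag_trial(20, 20, BagParams(p_s=0.8, p_a=0.5), seed=rng,
                           trial_id=f"t{i + 1}") for i in range(50)])


@pytest.fixture(scope="session")
def fitted_bag(bag_dataset):
    from bagforage.bag import BagForagingModel
    return BagForagingModel(random_state=7, **LIGHT_MCMC).fit(bag_dataset)


@pytest.fixture(scope="session")
def spatial_dataset():
    """15 uniform-layout trials at b_a=0.5, b_s=1, sigma_d=10, sigma_theta=-2."""
    rng = np.random.default_rng(5)
    params = SpatialParams(b_a=0.5, b_s=1.0, sigma_d=10.0, sigma_theta=-2.0)
    spec = StimulusSpec(layout="uniform", n_a=20, n_b=20)
    return Dataset([
        simulate_spatial_trial(make_stimulus(spec, seed=rng), params,
                               seed=rng, trial_id=f"t{i + 1}")
        for i in range(15)])


@pytest.fixture(scope="session")
def patchy_dataset():
    """20 patchy-layout trials with proximity bias only (sigma_d=15)."""
    rng = np.random.default_rng(42)
    params = SpatialParams(b_a=0.0, b_s=0.0, sigma_d=15.0, sigma_theta=0.0)
    spec = StimulusSpec(layout="patchy", n_a=20, n_b=20)
    return Dataset([
        simulate_spatial_trial(make_stimulus(spec, seed=rng), params,
                               seed=rng, trial_id=f"t{i + 1}")
        for i in range(20)])
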