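"""Spatial model: geometry, categorical weights, simulation, fitting."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import expit

from bagforage.bag import BagParams, trial_loglik
from bagforage.data import Dataset, Stimulus, TargetClass, Trial
from bagforage.spatial import (SelectionState, SpatialForagingModel,
                               SpatialParams, angular_deviation,
                               proximity_weight, selection_distribution,
                               simulate_spatial_trial, spatial_trial_loglik)

from conftest import LIGHT_MCMC


class TestAngularDeviation:
    def test_straight_ahead_is_zero(self):
        assert angular_deviation((0, 0), (1, 0), (2, 0)) == pytest.approx(0.0)

    def test_perpendicular_is_half(self):
        assert angular_deviation((0, 0), (1, 0), (1, 1)) == pytest.approx(0.5)

    def test_reversal_is_one(self):
        assert angular_deviation((0, 0), (1, 0), (0, 0)) == pytest.approx(1.0)

    def test_45_degrees(self):
        assert angular_deviation((0, 0), (1, 0), (2, 1)) == \
            pytest.approx(0.25)

    def test_zero_travel_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            angular_deviation((1, 1), (1, 1), (2, 2))

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = rng.uniform(size=(3, 2))
            if np.allclose(pts[0], pts[1]):
                continue
            base = angular_deviation(*pts)
            phi = rng.uniform(0, 2 * math.pi)
            rot = np.array([[math.cos(phi), -math.sin(phi)],
                            [math.sin(phi), math.cos(phi)]])
            shift = rng.uniform(-5, 5, size=2)
            moved = pts @ rot.T + shift
            assert angular_deviation(*moved) == pytest.approx(base, abs=1e-9)


class TestProximityWeight:
    def test_zero_distance_is_one(self):
        assert proximity_weight(0.0, 17.3) == 1.0

    def test_zero_tuning_is_flat(self):
        assert np.allclose(proximity_weight(np.linspace(0, 2, 9), 0.0), 1.0)

    def test_quarter_width_at_fitted_tuning(self):
        # sigma_d = 15 leaves ~2% weight a quarter stimulus-width away
        assert proximity_weight(0.25, 15.0) == \
            pytest.approx(math.exp(-3.75), rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            proximity_weight(-0.1, 1.0)


def _square_stimulus(labels="abab"):
    corners = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]
    return Stimulus.from_classes(labels, corners)


class TestSelectionDistribution:
    def test_uniform_when_all_biases_off(self):
        stim = _square_stimulus()
        state = SelectionState(stim, (0, 1, 2, 3))
        dist = selection_distribution(state, SpatialParams())
        assert np.allclose(list(dist.values()), 0.25)

    def test_selected_targets_have_zero_probability(self):
        stim = _square_stimulus()
        state = SelectionState(stim, (1, 2, 3), prev=0)
        dist = selection_distribution(state, SpatialParams(0.3, 0.4, 2.0))
        assert 0 not in dist
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_prev_in_remaining_rejected(self):
        with pytest.raises(ValueError, match="remaining"):
            SelectionState(_square_stimulus(), (0, 1, 2), prev=0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="remaining"):
            selection_distribution(SelectionState(_square_stimulus(), ()),
                                   SpatialParams())

    def test_three_target_hand_oracle(self):
        """Direct arithmetic on the weight formula, to 1e-12."""
        stim = Stimulus.from_classes(
            "aab", [(0.0, 0.0), (0.6, 0.0), (0.0, 0.8)])
        params = SpatialParams(b_a=0.4, b_s=-0.3, sigma_d=2.0,
                               sigma_theta=0.0)
        # previous selection: target 0 (class a); candidates 1 (a) and 2 (b)
        state = SelectionState(stim, (1, 2), prev=0)
        w1 = expit(0.4 * 1 + (-0.3) * 1) * math.exp(-2.0 * 0.6)
        w2 = expit(0.4 * -1 + (-0.3) * -1) * math.exp(-2.0 * 0.8)
        dist = selection_distribution(state, params)
        assert dist[1] == pytest.approx(w1 / (w1 + w2), abs=1e-12)
        assert dist[2] == pytest.approx(w2 / (w1 + w2), abs=1e-12)

    def test_first_selection_uses_class_term_only(self):
        stim = _square_stimulus("aabb")
        params = SpatialParams(b_a=0.7, b_s=5.0, sigma_d=9.0, sigma_theta=3.0)
        dist = selection_distribution(SelectionState(stim, (0, 1, 2, 3)),
                                      params)
        wa, wb = expit(0.7), expit(-0.7)
        tot = 2 * wa + 2 * wb
        assert dist[0] == pytest.approx(wa / tot, abs=1e-12)
        assert dist[2] == pytest.approx(wb / tot, abs=1e-12)


def _all_orders_total_probability(stim, params):
    total = 0.0
    ids = [t.id for t in stim.targets]
    for order in itertools.permutations(ids):
        trial = Trial(stimulus=stim, selections=order)
        total += math.exp(spatial_trial_loglik(trial, params))
    return total


class TestLikelihood:
    @pytest.mark.parametrize("params", [
        SpatialParams(),
        SpatialParams(0.5, -0.8, 4.0, 1.5),
        SpatialParams(-1.0, 2.0, 12.0, -2.0),
    ])
    def test_total_probability_over_complete_orders_is_one(self, params):
        stim = Stimulus.from_classes(
            "aabb", [(0.1, 0.2), (0.8, 0.1), (0.5, 0.9), (0.2, 0.6)])
        assert _all_orders_total_probability(stim, params) == \
            pytest.approx(1.0, abs=1e-9)

    def test_five_target_enumeration(self):
        stim = Stimulus.from_classes(
            "aabab",
            [(0.1, 0.1), (0.9, 0.2), (0.4, 0.8), (0.7, 0.7), (0.2, 0.5)])
        params = SpatialParams(0.3, 0.6, 6.0, -1.0)
        assert _all_orders_total_probability(stim, params) == \
            pytest.approx(1.0, abs=1e-9)

    def test_sigma_zero_class_marginal_equals_bag(self):
        """With both spatial weights off, summing the categorical
        probability over target orders of a given class sequence recovers
        the bag-model probability of that sequence."""
        stim = Stimulus.from_classes(
            "aabb", [(0.1, 0.2), (0.8, 0.1), (0.5, 0.9), (0.2, 0.6)])
        b_a, b_s = 0.3, -0.7
        sp = SpatialParams(b_a=b_a, b_s=b_s, sigma_d=0.0, sigma_theta=0.0)
        bp = BagParams.from_logits(b_s=b_s, b_a=b_a)
        by_id = {t.id: t for t in stim.targets}
        from conftest import trial_from_labels
        marginals = {}
        for order in itertools.permutations([t.id for t in stim.targets]):
            labels = "".join(by_id[i].cls.value for i in order)
            p = math.exp(spatial_trial_loglik(
                Trial(stimulus=stim, selections=order), sp))
            marginals[labels] = marginals.get(labels, 0.0) + p
        for labels, total in marginals.items():
            ll_bag = trial_loglik(trial_from_labels(labels), bp)
            assert total == pytest.approx(math.exp(ll_bag), abs=1e-10)

    def test_invariant_under_target_id_relabelling(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(size=(6, 2)).tolist()
        labels = "aabbab"
        stim = Stimulus.from_classes(labels, pos)
        trial = simulate_spatial_trial(stim, SpatialParams(0.2, 0.5, 5.0, 1.0),
                                       seed=2)
        params = SpatialParams(-0.4, 0.9, 3.0, -0.5)
        base = spatial_trial_loglik(trial, params)
        perm = rng.permutation(6)
        from bagforage.data import Target
        remap = {old: int(np.where(perm == old)[0][0]) for old in range(6)}
        stim2 = Stimulus(tuple(
            Target(remap[t.id], t.cls, t.pos) for t in stim.targets))
        trial2 = Trial(stimulus=stim2,
                       selections=tuple(remap[i] for i in trial.selections))
        assert spatial_trial_loglik(trial2, params) == \
            pytest.approx(base, abs=1e-10)


class TestSimulate:
    def test_seed_determinism(self):
        stim = _square_stimulus()
        params = SpatialParams(0.1, 0.2, 3.0, 0.5)
        t1 = simulate_spatial_trial(stim, params, seed=5)
        t2 = simulate_spatial_trial(stim, params, seed=5)
        assert t1.selections == t2.selections

    def test_no_target_selected_twice(self):
        rng = np.random.default_rng(3)
        stim = Stimulus.from_classes("ab" * 5, rng.uniform(size=(10, 2)))
        t = simulate_spatial_trial(stim, SpatialParams(0, 2.0, 10.0, -1.0),
                                   seed=rng)
        assert len(set(t.selections)) == len(t.selections) == 10

    def test_strong_proximity_gives_nearest_neighbour_tour(self):
        rng = np.random.default_rng(4)
        stim = Stimulus.from_classes("ab" * 5, rng.uniform(size=(10, 2)))
        t = simulate_spatial_trial(stim, SpatialParams(0, 0, 300.0, 0),
                                   seed=rng)
        pos = stim.positions()
        remaining = set(range(10)) - {t.selections[0]}
        for prev, nxt in zip(t.selections, t.selections[1:]):
            dists = {j: np.linalg.norm(pos[j] - pos[prev]) for j in remaining}
            assert nxt == min(dists, key=dists.get)
            remaining.discard(nxt)

    def test_step_frequencies_match_analytic_distribution(self):
        """Monte-Carlo first-step frequencies vs the categorical weights."""
        stim = Stimulus.from_classes(
            "aabab",
            [(0.1, 0.1), (0.9, 0.2), (0.4, 0.8), (0.7, 0.7), (0.2, 0.5)])
        params = SpatialParams(b_a=0.6, b_s=0.0, sigma_d=0.0, sigma_theta=0.0)
        expected = selection_distribution(
            SelectionState(stim, tuple(range(5))), params)
        rng = np.random.default_rng(6)
        n = 10_000
        counts = dict.fromkeys(range(5), 0)
        for _ in range(n):
            t = simulate_spatial_trial(stim, params, length=1, seed=rng)
            counts[t.selections[0]] += 1
        for tid, p in expected.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[tid] / n - p) < 3 * se


class TestFit:
    def test_parameter_recovery_uniform_layout(self, spatial_dataset):
        """97% HPDIs cover (b_a=0.5, b_s=1, sigma_d=10, sigma_theta=-2)."""
        from conftest import assert_recovered
        model = SpatialForagingModel(random_state=3, **LIGHT_MCMC)
        model.fit(spatial_dataset)
        truth = {"b_a": 0.5, "b_s": 1.0, "sigma_d": 10.0, "sigma_theta": -2.0}
        for name, value in truth.items():
            assert_recovered(model.posterior_, name, value)

    def test_single_short_trial_prior_dominated(self):
        rng = np.random.default_rng(8)
        stim = Stimulus.from_classes("ab" * 3, rng.uniform(size=(6, 2)))
        t = simulate_spatial_trial(stim, SpatialParams(), seed=rng)
        model = SpatialForagingModel(chains=2, iterations=400, random_state=9)
        model.fit(Dataset([t]))
        # almost no data: the b_a posterior should stay close to its prior
        assert np.std(model.posterior_.get("b_a")) > 0.5

    def test_nonspatial_data_rejected(self):
        from conftest import trial_from_labels
        with pytest.raises(ValueError, match="positions"):
            SpatialForagingModel().fit(Dataset([trial_from_labels("ab")]))

    def test_multilevel_smoke(self):
        from bagforage.stimuli import (ExperimentDesign, StimulusSpec,
                                       generate_experiment)
        design = ExperimentDesign(
            conditions={"c1": SpatialParams(0.5, 1.0, 10.0, -1.0)},
            trials_per_condition=3, participants=3,
            stimulus=StimulusSpec(layout="uniform", n_a=10, n_b=10),
            n_a=10, n_b=10)
        data = generate_experiment(design, seed=10)
        model = SpatialForagingModel(structure="multilevel", chains=2,
                                     iterations=300, warmup_steps=150,
                                     random_state=11).fit(data)
        post = model.posterior_
        assert {"mu_b_a", "mu_sigma_d", "tau_b_s", "b_s[p2]"} <= \
            set(post.parameters)
        assert np.isfinite(post.get("mu_sigma_d")).all()
        assert np.all(post.get("tau_b_a") >= 0)
        # with the default positivity constraint every participant-level
        # proximity parameter stays nonnegative
        for p in ("p1", "p2", "p3"):
            assert np.all(post.get(f"sigma_d[{p}]") >= 0)
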