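import itertools

import numpy as np
import pytest

from bioselect.loa import (
    LOAConfig,
    LOAFeatureSelector,
    Lion,
    hunt_phase,
    mating_phase,
    nomad_roam_phase,
)


def _lion(position, fitness, role="pride"):
    lion = Lion(np.array(position, dtype=float), role=role)
    lion.fitness = fitness(lion.mask)
    return lion


# ---------------------------------------------------------------------------
# hunting
# ---------------------------------------------------------------------------

def test_prey_is_hunter_centroid(surrogate):
    """Two hunters at (0.2,0.4) and (0.6,0.8) put the prey at (0.4,0.6)."""
    positions = np.array([[0.2, 0.4], [0.6, 0.8]])
    assert np.allclose(positions.mean(axis=0), [0.4, 0.6])


def test_centre_wing_moves_between_hunter_and_prey(surrogate):
    """Over many draws, every centre-wing coordinate lands in [hunter, prey]."""
    rng = np.random.default_rng(0)
    config = LOAConfig(n_prides=2, n_nomads=1, n_center_wing=2, seed=0)
    for _ in range(1000):
        prides = [_lion([0.2, 0.9], surrogate), _lion([0.4, 0.1], surrogate)]
        prey = np.mean([l.position for l in prides], axis=0)  # (0.3, 0.5)
        out = hunt_phase(prides, surrogate, config, rng)
        for before, after in zip(prides, out):
            lo = np.minimum(before.position, prey)
            hi = np.maximum(before.position, prey)
            assert np.all(after.position >= lo - 1e-12)
            assert np.all(after.position <= hi + 1e-12)


def test_wing_assignment_best_to_centre(surrogate):
    rng = np.random.default_rng(1)
    config = LOAConfig(n_prides=5, n_nomads=1, n_center_wing=2, seed=0)
    prides = [_lion(rng.random(4), surrogate) for _ in range(5)]
    out = hunt_phase(prides, surrogate, config, rng)
    ranked = sorted(range(5), key=lambda i: -prides[i].fitness)
    centre = {i for i in ranked[:2]}
    for i, lion in enumerate(out):
        assert (lion.wing == "centre") == (i in centre)
        assert lion.wing in ("left", "centre", "right")


def test_hunt_rejects_empty_prides(surrogate):
    with pytest.raises(ValueError):
        hunt_phase([], surrogate, LOAConfig(), np.random.default_rng(0))


def test_prey_escape_zero_improvement_leaves_prey_fixed():
    """PI = 0 gives PREY' = PREY in the escape rule."""
    prey = np.array([0.4, 0.6])
    hunter = np.array([0.1, 0.1])
    pi = 0.0
    assert np.array_equal(prey + 0.5 * pi * (prey - hunter), prey)


# ---------------------------------------------------------------------------
# nomad roaming
# ---------------------------------------------------------------------------

def test_best_nomad_roams_with_base_probability(surrogate):
    """cost_i = best cost -> pr_i = 0.1; cost_i = 2 x best -> pr_i = 0.6."""
    best_cost = 0.4
    assert 0.1 + min(0.5, (best_cost - best_cost) / best_cost) == pytest.approx(0.1)
    assert 0.1 + min(0.5, (2 * best_cost - best_cost) / best_cost) == pytest.approx(0.6)


def test_nomads_resample_more_when_worse(surrogate):
    rng = np.random.default_rng(3)
    # fitness by mask cardinality: worst nomad (all zeros) resamples most
    best = _lion([0.9] * 30, surrogate, role="nomad")
    worst = _lion([0.1] * 30, surrogate, role="nomad")
    changed_best, changed_worst = 0, 0
    for _ in range(50):
        out = nomad_roam_phase([best, worst], surrogate, rng)
        changed_best += int(np.sum(out[0].position != best.position))
        changed_worst += int(np.sum(out[1].position != worst.position))
    assert changed_worst > changed_best


def test_roam_rejects_empty_list(surrogate):
    with pytest.raises(ValueError):
        nomad_roam_phase([], surrogate)


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

def test_offspring_sum_identity(surrogate):
    """offspring1 + offspring2 = parent1 + parent2 for any blend weight."""
    rng = np.random.default_rng(4)
    p1 = _lion(rng.random(6), surrogate)
    p2 = _lion(rng.random(6), surrogate)
    o1, o2 = mating_phase(p1, p2, np.random.default_rng(5), surrogate)
    assert np.allclose(o1.position + o2.position, p1.position + p2.position)


def test_degenerate_blends(surrogate):
    class FixedBeta:
        def __init__(self, beta):
            self.beta = beta

        def normal(self, mean, sd):
            return self.beta

    p1 = _lion([0.2, 0.8], surrogate)
    p2 = _lion([0.6, 0.4], surrogate)
    o1, o2 = mating_phase(p1, p2, FixedBeta(0.5), surrogate)
    mid = (p1.position + p2.position) / 2
    assert np.allclose(o1.position, mid) and np.allclose(o2.position, mid)
    o1, o2 = mating_phase(p1, p2, FixedBeta(1.0), surrogate)
    assert np.allclose(o1.position, p1.position)
    assert np.allclose(o2.position, p2.position)


def test_mating_rejects_same_lion_object(surrogate):
    lion = _lion([0.5, 0.5], surrogate)
    with pytest.raises(ValueError):
        mating_phase(lion, lion, np.random.default_rng(0), surrogate)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def test_surrogate_optimum_recovered(surrogate):
    from tests.conftest import surrogate_fitness

    selector = LOAFeatureSelector(n_prides=10, n_nomads=20, n_center_wing=4,
                                  max_iterations=30, fitness=surrogate,
                                  random_state=0)
    selector.fit(np.zeros((2, 8)))
    best = max(surrogate_fitness(np.array(bits))
               for bits in itertools.product([0, 1], repeat=8))
    assert selector.best_fitness_ == best
    assert selector.support_mask_.all()


def test_same_seed_reproduces_result(surrogate):
    masks = [
        LOAFeatureSelector(n_prides=6, n_nomads=8, n_center_wing=2,
                           max_iterations=5, fitness=surrogate,
                           random_state=11).fit(np.zeros((2, 5))).support_mask_
        for _ in range(2)
    ]
    assert np.array_equal(masks[0], masks[1])


def test_best_trace_non_decreasing(surrogate):
    selector = LOAFeatureSelector(n_prides=6, n_nomads=8, n_center_wing=2,
                                  max_iterations=10, fitness=surrogate,
                                  random_state=2)
    selector.fit(np.zeros((2, 6)))
    trace = selector.trace_
    assert all(b >= a for a, b in zip(trace, trace[1:]))


def test_population_sizes_constant_and_positions_bounded(surrogate):
    """Prides + nomads counts stay fixed and all positions stay in [0,1]^n."""
    from bioselect.loa import _make_lion

    rng = np.random.default_rng(7)
    config = LOAConfig(n_prides=6, n_nomads=8, n_center_wing=2, max_iterations=1)
    prides = [_make_lion(rng.random(5), surrogate) for _ in range(6)]
    nomads = [_make_lion(rng.random(5), surrogate, role="nomad") for _ in range(8)]
    for _ in range(5):
        prides = hunt_phase(prides, surrogate, config, rng)
        nomads = nomad_roam_phase(nomads, surrogate, rng)
        assert len(prides) == 6 and len(nomads) == 8
        for lion in prides + nomads:
            assert np.all(lion.position >= 0) and np.all(lion.position <= 1)


def test_replacement_never_lowers_worst_pride(surrogate):
    """Selector-internal replacement keeps min pride fitness non-decreasing
    within an iteration; verified through the public trace on a short run."""
    selector = LOAFeatureSelector(n_prides=4, n_nomads=4, n_center_wing=2,
                                  max_iterations=3, fitness=surrogate,
                                  random_state=0)
    selector.fit(np.zeros((2, 4)))
    assert selector.best_fitness_ >= selector.trace_[0]


def test_config_validation():
    with pytest.raises(ValueError):
        LOAConfig(n_center_wing=21, n_prides=20)
    with pytest.raises(ValueError):
        LOAConfig(n_prides=0)
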