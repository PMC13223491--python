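"""Pelican optimizer: initialization, phase moves, convergence, fitness."""

import math

import numpy as np
import pytest

from vedicnn import poa_optimizer as poa
from vedicnn.poa_optimizer import (
    Bounds,
    Candidate,
    POAConfig,
    decode_candidate,
    exploitation_step,
    exploration_step,
    initialize,
    mask_fitness,
    optimize,
    rastrigin,
    sphere,
)


def box(m, lo=-5.0, hi=5.0):
    return Bounds(np.full(m, lo), np.full(m, hi))


class TestBounds:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            Bounds(np.array([0.0, 1.0]), np.array([1.0, 0.5]))

    def test_clamp(self):
        b = box(2, 0.0, 1.0)
        assert np.allclose(b.clamp(np.array([-3.0, 7.0])), [0.0, 1.0])


class TestInitialize:
    def test_positions_within_bounds(self):
        b = box(4)
        pop = initialize(b, POAConfig(pop_size=200, iterations=1, seed=3))
        pos = np.array([c.position for c in pop])
        assert np.all(pos >= b.lower) and np.all(pos <= b.upper)

    def test_deterministic_under_seed(self):
        b = box(3)
        p1 = initialize(b, POAConfig(pop_size=10, iterations=1, seed=9))
        p2 = initialize(b, POAConfig(pop_size=10, iterations=1, seed=9))
        assert all(np.array_equal(a.position, c.position)
                   for a, c in zip(p1, p2))

    def test_degenerate_narrow_bounds(self):
        b = Bounds(np.array([2.0]), np.array([2.0 + 1e-12]))
        pop = initialize(b, POAConfig(pop_size=5, iterations=1, seed=0))
        assert all(abs(c.position[0] - 2.0) < 1e-11 for c in pop)


class TestPhases:
    def test_greedy_acceptance_never_worsens(self):
        rng = np.random.default_rng(0)
        b = box(3)
        pop = initialize(b, POAConfig(pop_size=12, iterations=1, seed=1))
        for c in pop:
            c.fitness = sphere(c.position)
        before = [c.fitness for c in pop]
        prey = Candidate(pop[0].position.copy(), pop[0].fitness)
        exploration_step(pop, prey, sphere, b, rng)
        exploitation_step(pop, 1, 10, sphere, b, rng)
        assert all(a <= bb for a, bb in zip((c.fitness for c in pop), before))

    def test_final_iteration_exploitation_is_identity(self):
        rng = np.random.default_rng(1)
        b = box(3)
        pop = initialize(b, POAConfig(pop_size=6, iterations=1, seed=2))
        for c in pop:
            c.fitness = sphere(c.position)
        pos_before = [c.position.copy() for c in pop]
        exploitation_step(pop, 10, 10, sphere, b, rng)  # radius = 0
        assert all(np.array_equal(a, c.position)
                   for a, c in zip(pos_before, pop))

    def test_dispersion_shrinks_over_iterations(self):
        b = box(5)
        deltas = {1: [], 5: []}
        for seed in range(10):
            for t in deltas:
                rng = np.random.default_rng(100 + seed)
                pop = initialize(b, POAConfig(pop_size=8, iterations=1,
                                              seed=seed))
                for c in pop:
                    c.fitness = sphere(c.position)
                before = np.array([c.position for c in pop])
                exploitation_step(pop, t, 10, lambda _x: -1.0, b, rng)
                after = np.array([c.position for c in pop])
                deltas[t].append(np.mean(np.abs(after - before)))
        assert np.mean(deltas[5]) < np.mean(deltas[1])


class TestOptimize:
    def test_sphere_convergence_and_monotone_trace(self):
        bests = []
        for seed in range(5):
            best, trace = optimize(sphere, box(5),
                                   POAConfig(20, 100, seed=seed))
            assert all(a >= b for a, b in zip(trace, trace[1:]))
            bests.append(best.fitness)
        assert np.median(bests) < 1e-3

    def test_rastrigin_near_optimum(self):
        bests = [optimize(rastrigin, box(2, -5.12, 5.12),
                          POAConfig(20, 100, seed=s))[0].fitness
                 for s in range(5)]
        assert np.median(bests) < 1.0

    def test_constant_fitness_flat_trace_in_bounds(self):
        b = box(3)
        best, trace = optimize(lambda _x: 2.5, b, POAConfig(5, 10, seed=4))
        assert set(trace) == {2.5}
        assert np.all(best.position >= b.lower)
        assert np.all(best.position <= b.upper)

    def test_nan_fitness_rejected(self):
        calls = {"n": 0}

        def sometimes_nan(x):
            calls["n"] += 1
            return float("nan") if calls["n"] % 3 == 0 else sphere(x)

        best, trace = optimize(sometimes_nan, box(2), POAConfig(6, 20, seed=5))
        assert math.isfinite(best.fitness)
        assert all(math.isfinite(v) for v in trace)

    def test_determinism_under_seed(self):
        r1 = optimize(sphere, box(4), POAConfig(10, 30, seed=11))
        r2 = optimize(sphere, box(4), POAConfig(10, 30, seed=11))
        assert r1[1] == r2[1]
        assert np.array_equal(r1[0].position, r2[0].position)

    def test_warm_start_bounds_the_result(self):
        b = box(3)
        warm = np.array([0.01, 0.01, 0.01])
        best, _ = optimize(sphere, b, POAConfig(5, 5, seed=6),
                           warm_starts=[warm])
        assert best.fitness <= sphere(warm)


class TestFitness:
    def test_decode_rounds_to_valid_integers(self):
        hp = decode_candidate(np.array([-2.0, 6.7, 31.2, 0.55, 1.9]))
        assert hp == {"learning_rate": pytest.approx(0.01), "depth": 7,
                      "width": 31, "mask_threshold": 0.55, "radius": 2}

    def test_decode_clamps_out_of_range(self):
        hp = decode_candidate(np.array([-3.0, 99.0, 1.0, 0.9, -5.0]))
        assert hp["depth"] == 9 and hp["width"] == 8 and hp["radius"] == 0
        assert hp["mask_threshold"] == pytest.approx(0.8)

    def test_perfect_segmenter_scores_zero(self):
        rng = np.random.default_rng(7)
        masks = [(rng.random((8, 8)) > 0.5).astype(np.uint8)
                 for _ in range(4)]
        assert mask_fitness(masks, masks) == pytest.approx(0.0)

    def test_empty_prediction_on_nonempty_truth_scores_one(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[2:5, 2:5] = 1
        assert mask_fitness([np.zeros_like(truth)], [truth]) == \
            pytest.approx(1.0)

    def test_dncnn_fitness_runs_and_is_bounded(self, small_phantoms):
        train, test = small_phantoms
        pos = np.array([math.log10(2e-3), 3.0, 8.0, 0.5, 1.0])
        f = poa.dncnn_fitness(pos, train[:4], test[:2], epochs=2, seed=1)
        assert 0.0 <= f <= 1.0
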