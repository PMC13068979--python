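import math

import numpy as np
import pytest

from conftest import random_hubo
from latticefold.encoders import encode_coordinate, encode_turn_tetrahedral
from latticefold.fold import InteractionMatrix, Sequence, ground_truth_minimum
from latticefold.lattice import min_grid
from latticefold.polynomial import BinaryPolynomial, QuadraticModel
from latticefold.solvers import (
    AnnealSchedule,
    PTConfig,
    auto_start_temperature,
    exact_solve,
    greedy_coloring,
    metropolis_accept,
    parallel_tempering,
    simulated_annealing,
    turn_space_exact,
)


def random_qubo(rng, n=12, n_couplings=30):
    linear = {i: float(rng.normal()) for i in range(n)}
    quadratic = {}
    for _ in range(n_couplings):
        i, j = rng.choice(n, size=2, replace=False)
        key = (int(min(i, j)), int(max(i, j)))
        quadratic[key] = quadratic.get(key, 0.0) + float(rng.normal())
    return QuadraticModel(linear, quadratic)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, t, rng) for t in (0.01, 1.0, 100.0))

    def test_acceptance_frequency_at_de_equals_t(self, rng):
        n = 20_000
        accepted = sum(metropolis_accept(2.0, 2.0, rng) for _ in range(n)) / n
        assert accepted == pytest.approx(math.exp(-1), abs=0.02)

    def test_huge_barrier_rejected(self, rng):
        assert not any(metropolis_accept(1e6, 1.0, rng) for _ in range(100))

    def test_nonpositive_temperature(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestAutoStartTemperature:
    def test_deterministic(self, rng):
        model = random_qubo(rng)
        assert auto_start_temperature(model, seed=5) == auto_start_temperature(
            model, seed=5
        )

    def test_flat_model_fallback(self):
        model = QuadraticModel({0: 0.0, 1: 0.0}, {(0, 1): 0.0})
        assert auto_start_temperature(BinaryPolynomial({(0,): 0.0})) == 1.0

    def test_all_downhill_is_large(self):
        # strong uniform fields: from the all-ones state every flip is downhill
        model = QuadraticModel({i: 1000.0 for i in range(20)}, {})
        t0 = auto_start_temperature(model, n_probe=500, seed=1)
        assert t0 > 0

    def test_probe_floor(self):
        with pytest.raises(ValueError):
            auto_start_temperature(QuadraticModel({0: 1.0}, {}), n_probe=10)


class TestGreedyColoring:
    def test_edgeless(self):
        assert greedy_coloring(range(4), []) == [[0, 1, 2, 3]]

    def test_complete_graph(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        classes = greedy_coloring(range(4), edges)
        assert len(classes) == 4

    def test_proper_coloring(self, rng):
        edges = [
            (int(a), int(b))
            for a, b in rng.integers(0, 15, size=(40, 2))
            if a != b
        ]
        classes = greedy_coloring(range(15), edges)
        color = {v: c for c, cls in enumerate(classes) for v in cls}
        for i, j in edges:
            assert color[i] != color[j]
        assert sorted(v for cls in classes for v in cls) == list(range(15))


class TestExactSolve:
    def test_two_variable_model(self):
        model = QuadraticModel({0: -1.0, 1: -1.0}, {(0, 1): 2.0})
        energy, argmins = exact_solve(model)
        assert energy == -1.0
        assert sorted(tuple(sorted(a.items())) for a in argmins) == [
            ((0, 0), (1, 1)),
            ((0, 1), (1, 0)),
        ]

    def test_zero_model(self):
        energy, argmins = exact_solve(BinaryPolynomial({(0,): 0.0}))
        assert energy == 0.0
        assert argmins == [{}]

    def test_guard(self):
        model = QuadraticModel({i: 1.0 for i in range(30)}, {})
        with pytest.raises(ValueError, match="guard"):
            exact_solve(model)

    def test_hubo_supported(self):
        poly = BinaryPolynomial({(0, 1, 2): -2.0, (0,): 1.0})
        energy, argmins = exact_solve(poly)
        assert energy == -1.0
        assert argmins == [{0: 1, 1: 1, 2: 1}]


class TestSimulatedAnnealing:
    def test_single_variable(self):
        model = QuadraticModel({0: -1.0}, {})
        result = simulated_annealing(model, AnnealSchedule(sweeps=10), 3, seed=0)
        assert result.best_energy == -1.0
        assert result.best_assignment() == {0: 1}

    def test_matches_exact_on_random_qubos(self, rng):
        for seed in range(5):
            model = random_qubo(np.random.default_rng(seed))
            exact, _ = exact_solve(model)
            result = simulated_annealing(
                model, AnnealSchedule(zeta=0.99, sweeps=500), 20, seed=seed
            )
            assert result.best_energy == pytest.approx(exact)
            assert result.best_energy >= exact - 1e-9  # never below the oracle

    def test_determinism(self, rng):
        model = random_qubo(rng)
        schedule = AnnealSchedule(zeta=0.95, sweeps=100)
        a = simulated_annealing(model, schedule, 5, seed=9)
        b = simulated_annealing(model, schedule, 5, seed=9)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.energies, b.energies)

    def test_energies_match_reevaluation(self, rng):
        model = random_qubo(rng)
        result = simulated_annealing(model, AnnealSchedule(sweeps=50), 5, seed=2)
        for idx in range(len(result)):
            assert model.evaluate(result.assignment(idx)) == pytest.approx(
                result.energies[idx]
            )

    def test_coordinate_model_reaches_oracle(self, hp):
        seq = Sequence("HPPHPH")
        model = encode_coordinate(seq, min_grid(6, "diamond"), hp)
        result = simulated_annealing(
            model.poly, AnnealSchedule(t0=3.0, zeta=0.999, sweeps=1500), 30, seed=3
        )
        assert result.best_energy == ground_truth_minimum(seq, "diamond", hp)

    def test_hubo_fallback(self, rng):
        poly = random_hubo(rng, n_vars=8, n_terms=10, max_degree=3)
        exact, _ = exact_solve(poly)
        result = simulated_annealing(
            poly, AnnealSchedule(t0=2.0, zeta=0.99, sweeps=300), 10, seed=4
        )
        assert result.best_energy == pytest.approx(exact)

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            AnnealSchedule(zeta=1.5)
        with pytest.raises(ValueError):
            AnnealSchedule(t0=-1.0)


class TestParallelTempering:
    def test_matches_exact_on_random_qubos(self, rng):
        for seed in range(3):
            model = random_qubo(np.random.default_rng(100 + seed))
            exact, _ = exact_solve(model)
            result, _ = parallel_tempering(
                model, PTConfig(8, 0.1, 5.0, 800, 400, seed=seed)
            )
            assert result.best_energy == pytest.approx(exact)

    def test_determinism_and_energy_consistency(self, rng):
        model = random_qubo(rng)
        config = PTConfig(6, 0.2, 5.0, 200, 100, seed=7)
        a, trace_a = parallel_tempering(model, config, record_trace=True)
        b, trace_b = parallel_tempering(model, config, record_trace=True)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(trace_a, trace_b)
        for idx in range(len(a)):
            assert model.evaluate(a.assignment(idx)) == pytest.approx(a.energies[idx])

    def test_trace_shape(self, rng):
        model = random_qubo(rng, n=6, n_couplings=8)
        config = PTConfig(4, 0.5, 2.0, 100, 40, seed=0)
        _, trace = parallel_tempering(model, config, record_trace=True)
        assert trace.shape == (60, 6)

    def test_swap_rule(self):
        from latticefold.solvers.tempering import swap_probability

        # equal temperatures: always accepted (detailed-balance smoke test)
        assert swap_probability(3.7, 1.2, 2.0, 2.0) == 1.0
        # equal energies: exponent 0
        assert swap_probability(5.0, 5.0, 1.0, 3.0) == 1.0
        # hotter replica holds the lower energy: positive exponent
        assert swap_probability(2.0, 1.0, 0.5, 2.0) == 1.0
        # cold replica already lower: accepted with probability < 1
        assert 0.0 < swap_probability(1.0, 2.0, 0.5, 2.0) < 1.0

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            PTConfig(n_replicas=1)
        with pytest.raises(ValueError):
            PTConfig(t_min=2.0, t_max=1.0)
        config = PTConfig(5, 0.1, 10.0, 100, 10)
        ladder = config.ladder()
        assert np.all(np.diff(ladder) > 0)
        assert ladder[0] == pytest.approx(0.1) and ladder[-1] == pytest.approx(10.0)


class TestTurnSpaceExact:
    def test_all_p_minimum_zero(self, hp):
        model = encode_turn_tetrahedral(Sequence("PPPPPP"), hp, "dense")
        result = turn_space_exact(model)
        assert result.min_energy == 0.0

    def test_flaw_sequence_has_overlapping_minimizer(self, hp, flaw_sequence):
        model = encode_turn_tetrahedral(flaw_sequence, hp, "dense")
        result = turn_space_exact(model)
        assert any(not fold.is_valid for fold in result.folds)

    def test_minimum_not_above_valid_fold_oracle(self, hp):
        seq = Sequence("HPPPPH")
        model = encode_turn_tetrahedral(seq, hp, "dense")
        result = turn_space_exact(model)
        assert result.min_energy <= ground_truth_minimum(seq, "diamond", hp)

    def test_guard(self, hp):
        model = encode_turn_tetrahedral(Sequence("H" * 14), hp, "dense")
        with pytest.raises(ValueError, match="guard"):
            turn_space_exact(model)

    def test_requires_turn_model(self, hp):
        model = encode_coordinate(Sequence("HPPH"), min_grid(4, "cartesian"), hp)
        with pytest.raises(ValueError):
            turn_space_exact(model)
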