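import math

import numpy as np
import pytest

from latticefold.diagnostics import (
    OverlapDistribution,
    classify_barriers,
    estimate_sod,
    optimize_tts,
    qubo_metrics,
    spin_overlap,
    time_to_solution,
)
from latticefold.encoders import encode_coordinate
from latticefold.fold import InteractionMatrix, Sequence
from latticefold.lattice import min_grid
from latticefold.polynomial import QuadraticModel
from latticefold.solvers import AnnealSchedule, PTConfig, exact_solve


class TestSpinOverlap:
    def test_identical_states(self):
        assert spin_overlap([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_complementary_states(self):
        assert spin_overlap([1, 0, 1], [0, 1, 0]) == -1.0

    def test_one_of_four_differs(self):
        assert spin_overlap([1, 1, 1, 1], [1, 1, 1, 0]) == 0.5

    def test_mismatched_shapes(self):
        with pytest.raises(ValueError):
            spin_overlap([1, 0], [1, 0, 1])

    def test_overlap_grid(self, rng):
        n = 8
        for _ in range(10):
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            q = spin_overlap(a, b)
            assert -1.0 <= q <= 1.0
            assert any(
                q == pytest.approx((n - 2 * m) / n) for m in range(n + 1)
            )


class TestOverlapDistribution:
    def test_histogram_normalized(self, rng):
        dist = OverlapDistribution(rng.uniform(-1, 1, 500))
        _, masses = dist.histogram()
        assert masses.sum() == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            OverlapDistribution(np.array([1.5]))


class TestClassifyBarriers:
    def test_all_mass_at_one_is_thin(self):
        dist = OverlapDistribution(np.ones(200))
        assert classify_barriers(dist) == "thin"

    def test_peak_at_zero_is_thick(self, rng):
        dist = OverlapDistribution(rng.normal(0.0, 0.05, 500).clip(-1, 1))
        assert classify_barriers(dist) == "thick"

    def test_symmetric_outer_peaks_are_thin(self, rng):
        samples = np.concatenate(
            [rng.normal(0.9, 0.02, 300), rng.normal(-0.9, 0.02, 300)]
        ).clip(-1, 1)
        assert classify_barriers(OverlapDistribution(samples)) == "thin"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_barriers(OverlapDistribution(np.array([])))


@pytest.fixture(scope="module")
def coord_model(hp):
    seq = Sequence("HPPHPH")
    return encode_coordinate(seq, min_grid(6, "cartesian"), hp).poly.to_quadratic()


@pytest.fixture(scope="module")
def sod(coord_model):
    config = PTConfig(16, 0.1, 5.0, 3000, 2200, seed=0)
    return estimate_sod(coord_model, config, seeds=(11, 12))


class TestEstimateSod:
    def test_normalization_and_range(self, sod):
        _, masses = sod.histogram()
        assert masses.sum() == pytest.approx(1.0)
        assert np.all(sod.samples >= -1) and np.all(sod.samples <= 1)

    def test_discrete_spike_support(self, sod):
        # one-hot registers restrict overlaps to a few discrete values
        assert sod.support().size < sod.samples.size / 10

    def test_concentrates_near_full_overlap(self, sod):
        assert np.mean(np.abs(sod.samples) > 0.5) > 0.9

    def test_identical_seeds_rejected(self, coord_model):
        with pytest.raises(ValueError):
            estimate_sod(coord_model, PTConfig(4, 0.1, 1.0, 20, 10), seeds=(3, 3))

    def test_zero_field_ferromagnet_symmetric(self):
        # h = 0 Ising chain: P(q) symmetric under q -> -q within noise
        n = 6
        quad = QuadraticModel({}, {(i, i + 1): -1.0 for i in range(n - 1)})
        # shift to QUBO with fields cancelling: use the spin-symmetric QUBO
        # form 4bb' - 2b - 2b' (+1) per coupling so the Ising fields vanish
        quad = QuadraticModel(
            {i: 0.0 for i in range(n)},
            {(i, i + 1): 4.0 * -1.0 for i in range(n - 1)},
        )
        for i in range(n - 1):
            quad.linear[i] = quad.linear.get(i, 0.0) + 2.0
            quad.linear[i + 1] = quad.linear.get(i + 1, 0.0) + 2.0
        config = PTConfig(8, 0.2, 5.0, 4000, 2000, seed=0)
        samples = np.concatenate(
            [
                estimate_sod(quad, config, seeds=(2 * s, 2 * s + 1)).samples
                for s in range(4)
            ]
        )
        assert np.any(samples > 0.5) and np.any(samples < -0.5)
        assert abs(samples.mean()) < 0.5


class TestTimeToSolution:
    def test_p99_returns_tau(self):
        assert time_to_solution(7.0, 0.99) == 7.0
        assert time_to_solution(7.0, 1.0) == 7.0

    def test_half_probability(self):
        assert time_to_solution(1.0, 0.5) == pytest.approx(
            math.log(0.01) / math.log(0.5)
        )

    def test_zero_probability_infinite(self):
        assert time_to_solution(1.0, 0.0) == math.inf

    def test_monotone_decreasing_in_p(self):
        grid = np.linspace(0.01, 0.99, 50)
        values = [time_to_solution(3.0, p) for p in grid]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert all(v >= 3.0 for v in values)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            time_to_solution(0.0, 0.5)
        with pytest.raises(ValueError):
            time_to_solution(1.0, 1.5)


class TestOptimizeTts:
    def test_trivial_model(self):
        model = QuadraticModel({0: -1.0}, {})
        grid = [AnnealSchedule(sweeps=s) for s in (10, 50)]
        result = optimize_tts(model, -1.0, grid, n_repeats=10, seed=0)
        assert result.p_ground == 1.0
        assert result.tts == result.tau == 10  # cheapest schedule wins

    def test_bookkeeping_matches_recount(self, rng, hp):
        seq = Sequence("HPPH")
        model = encode_coordinate(seq, min_grid(4, "cartesian"), hp).poly.to_quadratic()
        grid = [AnnealSchedule(t0=2.0, zeta=0.99, sweeps=200)]
        result = optimize_tts(model, -1.0, grid, n_repeats=20, seed=1)
        assert 0.0 <= result.p_ground <= 1.0
        assert result.grid[0]["p_ground"] == result.p_ground

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            optimize_tts(QuadraticModel({0: -1.0}, {}), -1.0, [], 10, 0)

    def test_more_sweeps_do_not_hurt(self, hp):
        seq = Sequence("HPHPH")
        model = encode_coordinate(seq, min_grid(5, "cartesian"), hp).poly
        ground = -1.0
        grid = [AnnealSchedule(t0=2.0, zeta=0.999, sweeps=s) for s in (50, 400, 1500)]
        result = optimize_tts(model, ground, grid, n_repeats=30, seed=2)
        ps = [g["p_ground"] for g in result.grid]
        assert ps[-1] >= ps[0] - 0.15  # monotone up to sampling noise


class TestQuboMetrics:
    def test_diagonal_only(self):
        metrics = qubo_metrics(QuadraticModel({0: 1.0, 1: -2.0}, {}))
        assert metrics.density == 0.0
        assert metrics.couplers_per_variable == 0.0
        assert metrics.coupler_resolution == 1.0

    def test_all_pairs(self):
        quad = {(i, j): 1.0 for i in range(4) for j in range(i + 1, 4)}
        metrics = qubo_metrics(QuadraticModel({i: 1.0 for i in range(4)}, quad))
        assert metrics.density == 1.0
        assert metrics.couplers_per_variable == 3.0

    def test_resolution(self):
        quad = QuadraticModel({}, {(0, 1): 1.0, (1, 2): -4.0, (0, 2): 0.5})
        assert qubo_metrics(quad).coupler_resolution == 8.0
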