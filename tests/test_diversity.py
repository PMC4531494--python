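import math

import numpy as np
import pytest

from airrkit import (
    ClonotypeDefinition,
    ESConfig,
    SimulationConfig,
    div_model,
    estimate_repertoire_diversity,
    expected_unique,
    fit_diversity_model,
    rarefy,
    simulate_repertoire,
)
from airrkit.diversity import DiversityCurve


def curve_from_model(a, b, k, grid, noise_sd=0.0, seed=None):
    y = np.array([div_model(n, a, b, k) for n in grid], dtype=float)
    if noise_sd:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_sd * rng.normal(size=len(y)))
    return DiversityCurve(N=int(max(grid)), n_grid=list(grid), replicates=1,
                          replicate_counts=[[v] for v in y],
                          div_calc=list(y), seed=0)


class TestExpectedUnique:
    def test_single_clonotype(self):
        assert expected_unique([5], 1) == pytest.approx(1.0)

    def test_all_singletons_every_draw_is_new(self):
        assert expected_unique([1] * 30, 7) == pytest.approx(7.0)

    def test_two_clonotype_enumeration(self):
        # abundances [2,1], n=2: enumerate all C(3,2)=3 subsets -> mean 5/3
        assert expected_unique([2, 1], 2) == pytest.approx(5.0 / 3.0)

    def test_n_beyond_sample_rejected(self):
        with pytest.raises(ValueError):
            expected_unique([2, 2], 5)


class TestRarefy:
    def test_single_clonotype_always_one(self):
        curve = rarefy(["X"] * 40, [1, 10, 40], replicates=3, seed=0)
        assert all(c == 1 for counts in curve.replicate_counts for c in counts)

    def test_all_distinct_exhaustive_draw(self):
        keys = [f"k{i}" for i in range(25)]
        curve = rarefy(keys, [25], replicates=4, seed=0)
        assert curve.div_calc == [25.0]

    def test_zero_point_anchors_origin(self):
        curve = rarefy(["a", "b"], [0, 2], replicates=2, seed=0)
        assert curve.div_calc[0] == 0.0

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError, match="n=5"):
            rarefy(["a", "b"], [5], replicates=1, seed=0)

    def test_reproducible_from_seed(self):
        keys = [f"k{i % 7}" for i in range(100)]
        c1 = rarefy(keys, [10, 50], replicates=5, seed=9)
        c2 = rarefy(keys, [10, 50], replicates=5, seed=9)
        assert c1.replicate_counts == c2.replicate_counts

    def test_means_match_hypergeometric_expectation(self):
        # 50 clonotypes, abundances summing to 2000; 200 replicates must land
        # within 2% of the closed-form expectation
        abundances = [80 - i for i in range(50)]
        abundances = [max(a, 5) for a in abundances]
        keys = [f"K{i}" for i, a in enumerate(abundances) for _ in range(a)]
        grid = [100, 500, 1000]
        curve = rarefy(keys, grid, replicates=200, seed=7)
        for n, mean in zip(grid, curve.div_calc):
            expect = expected_unique(abundances, n)
            assert mean == pytest.approx(expect, rel=0.02)


class TestDivModel:
    def test_origin(self):
        assert div_model(0, 123.0, 0.01, 0.5) == 0.0

    def test_saturates_to_a_without_errors(self):
        assert div_model(1e9, 500.0, 1e-3, 0.0) == pytest.approx(500.0)

    def test_worked_value(self):
        # 100*(1-e^-1) + 0.001*100 = 63.3121 to 4 decimal places
        assert div_model(100, 100.0, 0.01, 0.001) == pytest.approx(63.3121,
                                                                   abs=5e-5)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            div_model(10, -1.0, 0.1, 0.0)

    def test_strictly_increasing_and_bounded(self):
        n = np.linspace(0, 1e5, 200)
        y = div_model(n, 800.0, 2e-4, 1e-3)
        assert np.all(np.diff(y) > 0)
        assert np.all(y <= 800.0 + 1e-3 * n + 1e-9)


class TestFit:
    def test_noiseless_recovery_within_one_percent(self):
        grid = range(0, 50_001, 1000)
        curve = curve_from_model(5000.0, 5e-4, 0.002, list(grid))
        fit = fit_diversity_model(curve, ESConfig(seed=3))
        assert fit.a == pytest.approx(5000.0, rel=0.01)
        assert fit.objective <= fit.initial_objective

    def test_noisy_recovery_median_within_five_percent(self):
        grid = list(range(0, 50_001, 1000))
        errors = []
        for s in range(20):
            curve = curve_from_model(5000.0, 5e-4, 0.002, grid,
                                     noise_sd=0.01, seed=1000 + s)
            fit = fit_diversity_model(curve, ESConfig(seed=s))
            errors.append(abs(fit.a - 5000.0) / 5000.0)
        assert float(np.median(errors)) < 0.05

    def test_flat_zero_curve_degenerates_cleanly(self):
        curve = DiversityCurve(N=40, n_grid=[0, 10, 20, 30, 40], replicates=1,
                               replicate_counts=[[0]] * 5,
                               div_calc=[0.0] * 5, seed=0)
        fit = fit_diversity_model(curve, ESConfig(seed=1))
        assert fit.objective == pytest.approx(0.0, abs=1e-12)
        assert fit.a * (1 - math.exp(-fit.b * 40)) + fit.k * 40 < 1e-6

    def test_same_seed_gives_bit_identical_fit(self):
        curve = curve_from_model(300.0, 1e-3, 0.01, list(range(0, 20_001, 500)))
        f1 = fit_diversity_model(curve, ESConfig(seed=5))
        f2 = fit_diversity_model(curve, ESConfig(seed=5))
        assert (f1.a, f1.b, f1.k, f1.objective) == (f2.a, f2.b, f2.k,
                                                    f2.objective)

    def test_too_few_grid_points_rejected(self):
        curve = curve_from_model(10.0, 0.1, 0.0, [0, 5, 10])
        with pytest.raises(ValueError):
            fit_diversity_model(curve)

    def test_best_objective_never_increases_across_generations(self):
        for seed in (0, 1, 2):
            curve = curve_from_model(1000.0, 3e-4, 0.005,
                                     list(range(0, 30_001, 1000)),
                                     noise_sd=0.02, seed=seed)
            fit = fit_diversity_model(curve, ESConfig(seed=seed))
            trace = np.array(fit.es_trace)
            assert np.all(np.diff(trace) <= 0.0)


class TestEndToEnd:
    def test_more_clonotypes_means_larger_fitted_a(self):
        # two samples at the same read depth: the one drawn from the richer
        # pool must get the larger diversity estimate
        fits = {}
        for rich, seed in ((1000, 21), (100, 22)):
            cfg = SimulationConfig(n_clonotypes=rich, n_reads=20_000,
                                   error_rate=0.001, seed=seed)
            records, _ = simulate_repertoire(cfg)
            _, fit = estimate_repertoire_diversity(
                records, n_step=500, config=ESConfig(generations=300, seed=seed))
            fits[rich] = fit.a
        assert fits[1000] > fits[100]

    def test_grid_includes_origin_and_n(self):
        cfg = SimulationConfig(n_clonotypes=20, n_reads=1503, error_rate=0.0,
                               functionality_mix=(1, 0, 0, 0), seed=4)
        records, _ = simulate_repertoire(cfg)
        curve, _ = estimate_repertoire_diversity(
            records, n_step=400, config=ESConfig(generations=50, seed=4))
        assert curve.n_grid[0] == 0 and curve.n_grid[-1] == curve.N == 1503

    def test_no_usable_keys_rejected(self, small_records):
        no_result_only = [small_records[4]]
        with pytest.raises(ValueError):
            estimate_repertoire_diversity(no_result_only,
                                          config=ESConfig(generations=10, seed=0))
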