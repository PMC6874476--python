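import numpy as np
import pytest

from colimit import (
    CommunityState,
    ModelConfig,
    SupplyVector,
    bin_yield_sweep,
    enumerate_uninvadable,
    generate_random_pool,
    infer_stability_from_multiplicity,
    monte_carlo_feasibility,
    multistability_histogram,
    multistability_vs_balance,
    pca_state_projection,
    richness_and_range_stats,
    yield_variation_sweep,
)
from conftest import equal_stoichiometry_pool
from test_stability import make_report


def small_pipeline(pool, n_samples=4_000, seed=2):
    cfg = ModelConfig(n_samples=n_samples, rng_seed=seed)
    states = enumerate_uninvadable(pool)
    report = monte_carlo_feasibility(pool, states, cfg)
    inf = infer_stability_from_multiplicity(report)
    return states, report, inf


class TestMultistabilityHistogram:
    def test_equal_stoichiometry_single_state_everywhere(self):
        pool = equal_stoichiometry_pool(2, 2, seed=0)
        states, report, inf = small_pipeline(pool)
        stats = multistability_histogram(report, inf.stable_mask)
        assert set(stats.histogram) == {1}
        assert stats.poisson_rate == 0.0
        assert stats.multistable_fraction == 0.0

    def test_poisson_rate_recovery_on_synthetic_counts(self):
        # V-1 ~ Poisson(0.1) planted directly into a synthetic report
        rng = np.random.default_rng(5)
        n, rate = 20_000, 0.1
        v = 1 + rng.poisson(rate, size=n)
        samples = [set(range(vi)) for vi in v]
        report = make_report(samples, n_states=int(v.max()))
        stats = multistability_histogram(
            report, np.ones(int(v.max()), bool)
        )
        se = np.sqrt(rate / n)
        assert abs(stats.poisson_rate - rate) < 3 * se
        assert sum(stats.histogram.values()) == n

    def test_histogram_accounts_every_sample(self, pool_2x2):
        states, report, inf = small_pipeline(pool_2x2)
        stats = multistability_histogram(report, inf.stable_mask)
        assert sum(stats.histogram.values()) == report.n_samples
        assert stats.V.min() >= 1


class TestBalanceScan:
    def test_fractions_bounded_and_counts_complete(self, pool_2x2):
        states, report, inf = small_pipeline(pool_2x2)
        stats = multistability_histogram(report, inf.stable_mask)
        scan = multistability_vs_balance(stats, n_bins=15)
        assert scan.n_samples.sum() == report.n_samples
        ok = scan.multistable_fraction.dropna()
        assert ((ok >= 0) & (ok <= 1)).all()

    def test_equal_stoichiometry_scan_is_zero(self):
        pool = equal_stoichiometry_pool(2, 2, seed=3)
        states, report, inf = small_pipeline(pool)
        stats = multistability_histogram(report, inf.stable_mask)
        scan = multistability_vs_balance(stats, n_bins=10)
        assert (scan.multistable_fraction.dropna() == 0).all()


class TestRichnessAndPrevalence:
    def test_tables_consistent(self, pool_2x2):
        states, report, inf = small_pipeline(pool_2x2)
        tables = richness_and_range_stats(
            report, states, inf.stable_mask, inf.unstable_mask, pool_2x2
        )
        counts = tables["counts_vs_richness"]
        assert counts.n_stable.sum() == inf.n_stable
        assert counts.n_unstable.sum() == inf.n_unstable
        prev = tables["prevalence"]
        assert ((prev.prevalence_any >= prev.prevalence_all)).all()
        assert ((prev.prevalence_any >= 0) & (prev.prevalence_any <= 1)).all()
        rvr = tables["richness_vs_ratio"]
        assert rvr.n_samples.sum() == report.n_samples

    def test_double_top_species_everywhere(self):
        # engineer a pool whose species 0 tops both of its resource columns;
        # it then appears in every feasible uninvadable state
        for seed in range(3):
            pool = generate_random_pool(2, 2, seed)
            ranks = __import__("colimit").competitiveness_ranks(pool)
            states, report, inf = small_pipeline(pool, n_samples=2_000)
            tables = richness_and_range_stats(
                report, states, inf.stable_mask, inf.unstable_mask, pool
            )
            prev = tables["prevalence"].set_index("species_id")
            for sid in prev.index[prev.average_rank == 1.0]:
                assert prev.loc[sid, "prevalence_any"] == 1.0
                assert prev.loc[sid, "prevalence_all"] == 1.0


class TestYieldSweep:
    def test_zero_stoichiometry_spread_never_multistable(self, pool_2x2):
        # degenerate interval: all yields equal, stoichiometry SD is 0
        sweep = yield_variation_sweep(
            pool_2x2,
            yield_intervals=((0.499999, 0.500001),),
            n_variants_per_interval=3,
            n_samples=2_000,
            seed=1,
        )
        assert (sweep.stoichiometry_log_sd < 1e-4).all()
        assert (sweep.multistable_fraction == 0).all()

    def test_sweep_table_and_binning(self, pool_2x2):
        sweep = yield_variation_sweep(
            pool_2x2,
            yield_intervals=((0.3, 0.7), (0.01, 1.0)),
            n_variants_per_interval=8,
            n_samples=2_000,
            seed=4,
        )
        assert len(sweep) == 16
        assert (sweep.multistable_fraction >= 0).all()
        wide = sweep[sweep.interval_low == 0.01].stoichiometry_log_sd
        narrow = sweep[sweep.interval_low == 0.3].stoichiometry_log_sd
        assert wide.mean() > narrow.mean()
        grid = bin_yield_sweep(sweep, n_bins=10)
        colsums = grid.sum(axis=0).dropna()
        np.testing.assert_allclose(
            colsums[colsums > 0], 100.0, rtol=1e-9
        )


class TestPCA:
    def test_multistable_neighbourhood_clusters(self, tilman_pool):
        states = enumerate_uninvadable(tilman_pool)
        cfg = ModelConfig(n_samples=2_000, rng_seed=0)
        report = monte_carlo_feasibility(tilman_pool, states, cfg)
        inf = infer_stability_from_multiplicity(report)
        centre = SupplyVector([100.0], [100.0], 1.0)
        df = pca_state_projection(
            tilman_pool, centre, states, inf.stable_mask, n_samples=50, seed=1
        )
        # both stable single-species states and the unstable coexistence
        # state are feasible throughout the overlap neighbourhood
        assert df.stable.sum() > 0 and (~df.stable).sum() > 0
        assert set(df.columns) >= {"pc1", "pc2", "state_id", "stable"}

    def test_projection_invariant_under_species_permutation(self, tilman_pool):
        from colimit import SpeciesPool

        states = enumerate_uninvadable(tilman_pool)
        cfg = ModelConfig(n_samples=1_000, rng_seed=0)
        report = monte_carlo_feasibility(tilman_pool, states, cfg)
        inf = infer_stability_from_multiplicity(report)
        centre = SupplyVector([100.0], [100.0], 1.0)
        df1 = pca_state_projection(
            tilman_pool, centre, states, inf.stable_mask, n_samples=30, seed=2
        )
        permuted = SpeciesPool(
            1, 1, tuple(reversed(tilman_pool.species))
        )
        df2 = pca_state_projection(
            permuted, centre, states, inf.stable_mask, n_samples=30, seed=2
        )
        for col in ("pc1", "pc2"):
            same = np.allclose(df1[col], df2[col], atol=1e-9)
            flipped = np.allclose(df1[col], -df2[col], atol=1e-9)
            assert same or flipped

    def test_too_few_samples_rejected(self, tilman_pool):
        states = enumerate_uninvadable(tilman_pool)
        centre = SupplyVector([100.0], [100.0], 1.0)
        with pytest.raises(ValueError):
            pca_state_projection(
                tilman_pool, centre, states,
                np.ones(len(states), bool), n_samples=2,
            )
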