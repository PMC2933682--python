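"""Synthetic-cohort generator: calibration, populations, deaths, datasets."""

import io

import numpy as np
import pytest

from geostruct import (
    DomainError,
    SimulationConfig,
    SimulationError,
    calibrate_lognormal_sigma,
    generate_dataset,
    generate_deaths,
    generate_region_populations,
    gini,
    region_summaries,
    split_population_by_age,
)
from geostruct.standardize import write_table


class TestCalibrateLognormalSigma:
    def test_zero_gini_is_degenerate(self):
        assert calibrate_lognormal_sigma(0.0) == 0.0

    @pytest.mark.parametrize("target,expected", [(0.3, 0.5449), (0.5, 0.9539)])
    def test_monte_carlo_gini_of_calibrated_lognormal(self, target, expected, rng):
        """The calibrated sigma must reproduce the target Gini in a large
        log-normal sample (frozen oracle values 0.5449 / 0.9539)."""
        sigma = calibrate_lognormal_sigma(target)
        assert sigma == pytest.approx(expected, abs=2e-4)
        draws = rng.lognormal(0.0, sigma, size=10**6)
        assert gini(draws) == pytest.approx(target, abs=2e-3)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            calibrate_lognormal_sigma(bad)


class TestGenerateRegionPopulations:
    def test_zero_gini_gives_equal_populations(self):
        pops = generate_region_populations(9, 388_511, 0.0, seed=1)
        assert np.all(pops == 388_511.0)
        assert gini(pops) == 0.0

    def test_realized_gini_within_tolerance(self):
        pops = generate_region_populations(20, 1e6, 0.4, tolerance=0.02, seed=5)
        assert 0.38 <= gini(pops) <= 0.42

    def test_mean_is_rescaled_exactly(self):
        pops = generate_region_populations(20, 1e6, 0.4, tolerance=0.02, seed=5)
        assert pops.mean() == pytest.approx(1e6, abs=0.5)
        assert np.all(pops > 0)

    def test_deterministic_given_seed(self):
        a = generate_region_populations(15, 2e5, 0.3, seed=11)
        b = generate_region_populations(15, 2e5, 0.3, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_retry_exhaustion_names_achieved_gini(self):
        with pytest.raises(SimulationError, match="closest"):
            generate_region_populations(
                2, 1e5, 0.9, tolerance=1e-6, seed=0, max_retries=5
            )

    def test_positive_gini_needs_two_regions(self):
        with pytest.raises(DomainError):
            generate_region_populations(1, 1e5, 0.2, seed=0)


class TestSplitPopulationByAge:
    def test_uniform_schedule(self):
        out = split_population_by_age(1000.0, np.full(14, 1 / 14))
        np.testing.assert_allclose(out, 1000 / 14)

    def test_conservation_and_hand_bands(self):
        schedule = np.zeros(14)
        schedule[[0, 5, 13]] = [0.25, 0.35, 0.40]
        out = split_population_by_age(388_511, schedule)
        assert out.sum() == pytest.approx(388_511, abs=1e-6)
        assert out[0] == pytest.approx(388_511 * 0.25)
        assert out[5] == pytest.approx(388_511 * 0.35)
        assert out[13] == pytest.approx(388_511 * 0.40)

    def test_negative_proportion_rejected(self):
        schedule = np.full(14, 1 / 14)
        schedule[0], schedule[1] = -0.01, schedule[1] + 0.01 + 1 / 14
        with pytest.raises(DomainError):
            split_population_by_age(100.0, schedule)


class TestGenerateDeaths:
    def test_zero_rates_give_zero_counts(self, rng):
        out = generate_deaths(np.full(14, 1e4), np.zeros(14), 0.1, 0.2, 0.3, seed=rng)
        assert np.all(out == 0)

    def test_monte_carlo_mean_matches_expectation(self, rng):
        """With all effects zero, the count mean over many replicates is
        pop x rate within 3 Monte-Carlo standard errors."""
        pop, rate, n = 5_000.0, 0.002, 100_000
        mu = pop * rate
        pkg = generate_deaths(
            np.full(n, pop), np.full(n, rate), 0.0, 0.0, 0.0, seed=42
        )
        se = np.sqrt(mu / n)
        assert pkg.mean() == pytest.approx(mu, abs=3 * se)
        # and the distribution's variance is Poisson-consistent
        assert pkg.var() == pytest.approx(mu, rel=0.05)

    def test_log_scale_effects_multiply_expectation(self):
        """u = log 2 doubles the Monte-Carlo mean."""
        n, pop, rate = 200_000, 2_000.0, 0.003
        base = generate_deaths(np.full(n, pop), np.full(n, rate), 0.0, 0.0, 0.0, seed=9)
        doubled = generate_deaths(
            np.full(n, pop), np.full(n, rate), 0.0, 0.0, np.log(2.0), seed=10
        )
        ratio = doubled.mean() / base.mean()
        assert ratio == pytest.approx(2.0, rel=0.02)


class TestGenerateDataset:
    def test_pure_poisson_when_all_effects_zero(self):
        config = SimulationConfig(
            n_countries=2, regions_per_country=4, target_gini=0.0,
            mean_region_pop=5e5, sigma_u_true=0.0, variance_structure_true=None,
            beta0_true=0.0, sigma_v_true=0.0, seed=3,
        )
        table, truth = generate_dataset(config)
        assert np.all(truth.nu == 0.0)
        assert np.all(truth.u["u"] == 0.0)
        # each band's count has the plain reference expectation
        merged = table.groupby("age_band")[["population", "deaths"]].sum()
        exp = merged["population"].to_numpy() * config.reference_rates_true
        z = (merged["deaths"].to_numpy() - exp) / np.sqrt(exp)
        assert np.all(np.abs(z) < 5)

    def test_log_smr_dispersion_grows_with_sigma_u(self):
        """Across replicates, the empirical SD of log SMR increases with
        the generating within-country sigma_u."""
        sds = []
        for sigma_u in (0.05, 0.1, 0.2):
            reps = []
            for rep in range(200):
                config = SimulationConfig(
                    n_countries=1, regions_per_country=30, target_gini=0.2,
                    mean_region_pop=3e5, sigma_u_true=sigma_u,
                    variance_structure_true=None, sigma_v_true=0.0,
                    seed=10_000 + rep,
                )
                table, _ = generate_dataset(config)
                s = region_summaries(table)
                reps.append(np.log(s.smr).std(ddof=1))
            sds.append(np.mean(reps))
        assert sds[0] < sds[1] < sds[2]

    def test_dimensions_truth_and_runtime(self):
        import time

        t0 = time.time()
        config = SimulationConfig(
            n_countries=20, regions_per_country=10, target_gini=(0.1, 0.5),
            mean_region_pop=4e5, seed=1,
        )
        table, truth = generate_dataset(config)
        assert time.time() - t0 < 5.0
        assert len(table) == 20 * 10 * 14
        assert truth.nu.shape == (20,)
        assert truth.sigma_u.shape == (20,)
        assert len(truth.u) == 200
        # truth region ordering matches the emitted table
        table_regions = table[["country_id", "region_id"]].drop_duplicates()
        assert table_regions.reset_index(drop=True).equals(
            truth.u[["country_id", "region_id"]]
        )

    def test_realized_gini_within_tolerance_every_country(self, small_dataset):
        config, table, truth = small_dataset
        from geostruct import country_structure_table

        struct = country_structure_table(table)
        lo, hi = 0.1, 0.5
        targets = np.linspace(lo, hi, config.n_countries)
        assert np.all(np.abs(struct.gini.to_numpy() - targets)
                      <= config.gini_tolerance + 1e-12)

    def test_seed_determinism_is_byte_identical(self, small_dataset):
        config, table, _ = small_dataset
        table2, _ = generate_dataset(config)
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_table(table, buf1)
        write_table(table2, buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_variance_structure_generates_from_realized_covariates(self):
        config = SimulationConfig(
            n_countries=6, regions_per_country=12, target_gini=(0.1, 0.5),
            mean_region_pop=3e5, variance_structure_true=3,
            beta1_true=-2.7, beta2_true=1.3, sigma_r_true=0.0, seed=21,
        )
        _, truth = generate_dataset(config)
        np.testing.assert_allclose(
            truth.sigma_u, np.exp(-2.7 + 1.3 * truth.gini), rtol=1e-12
        )

    def test_linear_structure_floor_truncation(self, caplog):
        config = SimulationConfig(
            n_countries=3, regions_per_country=8, target_gini=0.2,
            mean_region_pop=2e5, variance_structure_true=5,
            beta1_true=-1.0, beta2_true=0.1, seed=2,
        )
        with caplog.at_level("WARNING"):
            _, truth = generate_dataset(config)
        assert np.all(truth.sigma_u == 1e-4)
        assert "truncated" in caplog.text
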