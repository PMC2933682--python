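"""Variance-structure models: specs, log-joint, diagnostics, DIC, sampling."""

import numpy as np
import pandas as pd
import pytest

from geostruct import (
    DomainError,
    MCMCConfig,
    ModelData,
    PosteriorState,
    SimulationConfig,
    country_structure_table,
    generate_dataset,
    region_summaries,
)
from geostruct.model import (
    FitResult,
    deviance,
    dic_from_draws,
    gelman_rubin,
    log_joint,
    make_model_spec,
    poisson_loglik,
    sample_posterior,
)


def make_data(n_countries=3, n_regions=5, seed=0):
    rng = np.random.default_rng(seed)
    J, n = n_countries, n_regions
    observed = rng.poisson(50, size=J * n).astype(float)
    expected = np.full(J * n, 50.0)
    ci = np.repeat(np.arange(J), n)
    return ModelData(
        observed=observed,
        expected=expected,
        country_index=ci,
        gini=np.linspace(0.1, 0.5, J),
        size_m=np.linspace(0.2, 2.0, J),
        country_ids=[f"c{j}" for j in range(J)],
    )


def default_state(data, sigma_u=0.1):
    return PosteriorState(
        beta0=0.0,
        nu=np.zeros(data.n_countries),
        u=np.zeros(data.n_regions),
        sigma_v=0.3,
        sigma_u=np.full(data.n_countries, sigma_u),
        beta1=np.log(sigma_u),
        beta2=0.0,
        beta3=0.0,
        sigma_r=0.1,
    )


class TestMakeModelSpec:
    def test_baseline_random(self):
        spec = make_model_spec(1)
        assert spec.link == "random" and spec.covariates == ()

    def test_log_deterministic_gini(self):
        spec = make_model_spec(3)
        assert spec.link == "log"
        assert spec.covariates == ("G",)
        assert not spec.residual_fitted

    def test_linear_combined_fitted(self):
        spec = make_model_spec(11)
        assert spec.link == "linear"
        assert spec.covariates == ("G", "R")
        assert spec.residual_fitted

    @pytest.mark.parametrize("bad", [0, 12, "x", None])
    def test_unknown_variant(self, bad):
        with pytest.raises(DomainError):
            make_model_spec(bad)


class TestLogJoint:
    def test_single_region_poisson_term_by_hand(self):
        data = ModelData(
            observed=[2.0], expected=[2.0], country_index=[0],
            gini=[0.3], size_m=[0.5], country_ids=["c0"],
        )
        # log Poisson(2; 2) = 2 log 2 - 2 - log 2!
        expected = 2 * np.log(2) - 2 - np.log(2)
        assert poisson_loglik(data, 0.0, np.zeros(1), np.zeros(1)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(-1.3069, abs=5e-4)
        # independent oracle
        from scipy.stats import poisson

        assert expected == pytest.approx(poisson.logpmf(2, 2), abs=1e-12)

    def test_offset_symmetry_of_likelihood(self):
        data = make_data()
        nu = np.linspace(-0.2, 0.2, data.n_countries)
        u = np.zeros(data.n_regions)
        c = 0.37
        base = poisson_loglik(data, 0.5, nu, u)
        shifted = poisson_loglik(data, 0.5 + c, nu - c, u)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_sigma_v_outside_uniform_support(self):
        data = make_data()
        state = default_state(data)
        state.sigma_v = 1.5
        assert log_joint(state, data, make_model_spec(3)) == -np.inf

    def test_model1_sigma_u_outside_unit_interval(self):
        data = make_data()
        state = default_state(data)
        state.sigma_u = np.full(data.n_countries, 1.2)
        assert log_joint(state, data, make_model_spec(1)) == -np.inf

    def test_linear_floor_enforced(self):
        data = make_data()
        state = default_state(data, sigma_u=5e-5)
        assert log_joint(state, data, make_model_spec(5)) == -np.inf

    def test_nonfinite_inputs_return_neg_inf_not_raise(self):
        data = make_data()
        state = default_state(data)
        state.beta0 = np.nan
        assert log_joint(state, data, make_model_spec(3)) == -np.inf
        state = default_state(data)
        state.u = np.full(data.n_regions, np.inf)
        assert log_joint(state, data, make_model_spec(3)) == -np.inf

    def test_finite_in_support_and_decomposable(self):
        data = make_data()
        spec = make_model_spec(2)
        state = default_state(data)
        lp = log_joint(state, data, spec)
        assert np.isfinite(lp)
        # adding the same c to beta0 and subtracting from nu changes only priors
        state2 = default_state(data)
        state2.beta0 += 0.2
        state2.nu = state2.nu - 0.2
        diff = log_joint(state2, data, spec) - lp
        prior_diff = (
            -0.5 * np.sum((state2.nu / state2.sigma_v) ** 2)
            + 0.5 * np.sum((state.nu / state.sigma_v) ** 2)
        )
        assert diff == pytest.approx(prior_diff, abs=1e-9)


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self, rng):
        chain = rng.normal(size=10_000)
        assert gelman_rubin([chain, chain]) == pytest.approx(1.0, abs=1e-9)

    def test_same_distribution_chains_converge(self, rng):
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_flagged(self, rng):
        a = rng.normal(0.0, 1.0, 5_000)
        b = rng.normal(10.0, 1.0, 5_000)
        assert gelman_rubin([a, b]) > 5.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(DomainError):
            gelman_rubin(rng.normal(size=(1, 100)))

    def test_agrees_with_arviz_on_mixed_chains(self, rng):
        import arviz as az

        chains = rng.normal(size=(4, 2_000))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(az.from_dict({"x": chains}))["x"].item())
        assert abs(ours - theirs) < 0.01


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self):
        data = make_data()
        beta0 = np.full(50, 0.1)
        nu = np.tile(np.linspace(-0.1, 0.1, data.n_countries), (50, 1))
        u = np.zeros((50, data.n_regions))
        dic, pd_, dbar = dic_from_draws(data, beta0, nu, u)
        assert pd_ == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(deviance(data, 0.1, nu[0], u[0]), abs=1e-9)

    def test_matches_brute_force_on_fixed_fake_draws(self, rng):
        data = make_data()
        S = 40
        beta0 = rng.normal(0, 0.05, S)
        nu = rng.normal(0, 0.1, (S, data.n_countries))
        u = rng.normal(0, 0.1, (S, data.n_regions))
        dic, pd_, dbar = dic_from_draws(data, beta0, nu, u)
        devs = np.array([deviance(data, beta0[s], nu[s], u[s]) for s in range(S)])
        dbar_bf = devs.mean()
        dhat_bf = deviance(data, beta0.mean(), nu.mean(0), u.mean(0))
        assert dbar == pytest.approx(dbar_bf, rel=1e-12)
        assert pd_ == pytest.approx(dbar_bf - dhat_bf, rel=1e-9)
        assert dic == pytest.approx(2 * dbar_bf - dhat_bf, rel=1e-9)
        assert pd_ > 0  # dispersed draws imply positive effective parameters


def simulate_fit_data(seed, sigma_u=0.1, n_countries=6, n_regions=15):
    config = SimulationConfig(
        n_countries=n_countries, regions_per_country=n_regions,
        target_gini=(0.1, 0.5), mean_region_pop=4e5,
        sigma_u_true=sigma_u, variance_structure_true=None,
        sigma_v_true=0.36, seed=seed,
    )
    table, truth = generate_dataset(config)
    summaries = region_summaries(table)
    struct = country_structure_table(table)
    return ModelData.from_frames(summaries, struct), truth


class TestSamplePosterior:
    def test_variant1_recovers_constant_sigma_u(self):
        data, truth = simulate_fit_data(seed=31, sigma_u=0.1)
        fit = sample_posterior(data, make_model_spec(1), MCMCConfig.desk(seed=2))
        med = fit.sigma_u_summary["median"].to_numpy()
        assert np.all(med > 0.04) and np.all(med < 0.22)
        assert fit.converged

    def test_posterior_support_respected_in_draws(self):
        data, _ = simulate_fit_data(seed=31, sigma_u=0.1)
        fit = sample_posterior(data, make_model_spec(1), MCMCConfig.desk(seed=2))
        sv = fit.chains["sigma_v"]
        assert np.all((sv > 0) & (sv < 1))
        assert np.all(fit.sigma_u_chains > 0) and np.all(fit.sigma_u_chains < 1)

    def test_two_seeds_agree_within_monte_carlo_error(self):
        import arviz as az

        data, _ = simulate_fit_data(seed=55, sigma_u=0.12)
        spec = make_model_spec(3)
        f1 = sample_posterior(data, spec, MCMCConfig.desk(seed=101))
        f2 = sample_posterior(data, spec, MCMCConfig.desk(seed=202))
        for name in ("beta0", "sigma_v", "beta2"):
            m1, m2 = f1.param_median(name), f2.param_median(name)
            mcse = 0.0
            for f in (f1, f2):
                ess = float(az.ess(az.from_dict({name: f.chains[name]}))[name].item())
                mcse += f.chains[name].std() / np.sqrt(max(ess, 1.0))
            # median MCSE ~ 1.25x mean MCSE for a normal; allow 2x combined
            assert abs(m1 - m2) < 2.0 * 1.5 * mcse + 1e-3

    def test_offset_scaling_shifts_beta0(self):
        """Multiplying every E by c must shift the beta0 posterior by -log c."""
        data, _ = simulate_fit_data(seed=77, sigma_u=0.1)
        c = 3.0
        scaled = ModelData(
            observed=data.observed, expected=data.expected * c,
            country_index=data.country_index, gini=data.gini,
            size_m=data.size_m, country_ids=data.country_ids,
        )
        spec = make_model_spec(1)
        f1 = sample_posterior(data, spec, MCMCConfig.desk(seed=5))
        f2 = sample_posterior(scaled, spec, MCMCConfig.desk(seed=5))
        shift = f1.param_median("beta0") - f2.param_median("beta0")
        assert shift == pytest.approx(np.log(c), abs=0.05)

    def test_nonconvergence_is_flagged_not_raised(self):
        data, _ = simulate_fit_data(seed=31, sigma_u=0.1, n_countries=4, n_regions=8)
        mcmc = MCMCConfig(n_chains=2, burn_in=120, n_keep=150, seed=0)
        fit = sample_posterior(data, make_model_spec(2), mcmc)
        assert isinstance(fit, FitResult)
        assert isinstance(fit.converged, bool)


class TestFitAllVariants:
    def test_one_row_per_variant_and_round_trip(self, tmp_path, small_dataset):
        from geostruct.model import fit_all_variants

        _, table, _ = small_dataset
        summaries = region_summaries(table)
        struct = country_structure_table(table)
        data = ModelData.from_frames(summaries, struct)
        mcmc = MCMCConfig(n_chains=2, burn_in=400, n_keep=800, seed=3)
        comparison, fits = fit_all_variants(data, [1, 3], mcmc)
        assert list(comparison["variant"]) == [1, 3]
        assert comparison.loc[comparison.variant == 1, "delta_dic"].iloc[0] == 0.0
        path = tmp_path / "comparison.tsv"
        comparison.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(
            back, comparison.reset_index(drop=True), check_exact=False, atol=1e-9
        )
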