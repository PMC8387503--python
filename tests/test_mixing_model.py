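"""Tests of the mixing model: moments, likelihood (vs a quadrature oracle),
ILR transform (vs scikit-bio), convergence diagnostics, and the sampler's
structural contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from trophoniche.mixing_model import (
    ConvergenceReport,
    MixingConfig,
    MixingError,
    SourceDistribution,
    TDFSpec,
    fit_mixing_model,
    gelman_rubin,
    geweke,
    ilr,
    ilr_inv,
    log_likelihood,
    mixture_moments,
    summarize_posterior,
)
from conftest import make_k3_scenario
from trophoniche.synthetic_data import generate_consumers


class TestMixtureMoments:
    def test_single_source_moments(self):
        src = [SourceDistribution("ak", (-18.7, 9.3), (0.3, 0.6), 28)]
        mean, var = mixture_moments([1.0], src, TDFSpec())
        assert mean[1] == pytest.approx(11.0)
        assert var[1] == pytest.approx(0.61)  # 0.6^2 + 0.5^2
        assert mean[0] == pytest.approx(-17.7)

    def test_even_mix_zero_sd(self):
        src = [
            SourceDistribution("ak", (-18.7, 9.3), (0.0, 0.0)),
            SourceDistribution("cap", (-18.7, 12.4), (0.0, 0.0)),
        ]
        mean, var = mixture_moments([0.5, 0.5], src, TDFSpec(1.0, 0.0, 1.7, 0.0))
        assert mean[1] == pytest.approx(12.55)
        assert var[1] == pytest.approx(0.0)

    def test_identical_sources_make_moments_p_invariant(self, rng):
        src = [SourceDistribution("a", (-19.0, 10.0), (0.4, 0.3))] * 3
        base = mixture_moments([1 / 3] * 3, src, TDFSpec())
        for _ in range(5):
            p = rng.dirichlet(np.ones(3))
            mean, var = mixture_moments(p, src, TDFSpec())
            assert mean == pytest.approx(base[0])
            # variance depends on p only through sum p^2 for identical sources
        vertex = mixture_moments([1.0, 0.0, 0.0], src, TDFSpec())
        assert vertex[0] == pytest.approx(base[0])

    def test_dimension_mismatch_rejected(self):
        src = [SourceDistribution("a", (-19.0, 10.0), (0.4, 0.3))]
        with pytest.raises(MixingError):
            mixture_moments([0.5, 0.5], src, TDFSpec())

    def test_off_simplex_rejected(self):
        src = [SourceDistribution("a", (-19.0, 10.0), (0.4, 0.3))] * 2
        with pytest.raises(MixingError):
            mixture_moments([0.7, 0.7], src, TDFSpec())


class TestLogLikelihood:
    def test_value_at_mode_with_unit_variances(self):
        # sd^2 + tau^2 = 1 for both tracers -> density at the mode is
        # (2*pi)^-1 over the two tracers
        sd = np.sqrt(0.75)
        src = [SourceDistribution("a", (-19.0, 10.0), (sd, sd))]
        val = log_likelihood([-18.0, 11.7], [1.0], src, TDFSpec())
        assert val == pytest.approx(-np.log(2 * np.pi))

    def test_monotone_decay_from_the_mode(self):
        src = [SourceDistribution("a", (-19.0, 10.0), (0.4, 0.3))]
        tdf = TDFSpec()
        lls = [
            log_likelihood([-18.0 + d, 11.7], [1.0], src, tdf) for d in (0.0, 0.5, 1.0, 2.0)
        ]
        assert np.all(np.diff(lls) < 0)

    def test_matches_quadrature_oracle(self):
        # marginal density of x = mu~ + lambda~ with mu~ ~ N(mu, sigma^2) and
        # lambda~ ~ N(lambda, tau^2), computed by numeric convolution
        mu, sigma = -19.0, 0.4
        lam, tau = 1.0, 0.5
        mu_n, sigma_n = 10.0, 0.3
        lam_n, tau_n = 1.7, 0.5
        src = [SourceDistribution("a", (mu, mu_n), (sigma, sigma_n))]
        x = np.array([-17.6, 11.2])

        def marginal(xi, m, s, l, t):
            f = lambda u: stats.norm.pdf(xi - u, m, s) * stats.norm.pdf(u, l, t)
            val, _ = integrate.quad(f, l - 10 * t, l + 10 * t, epsabs=1e-12)
            return val

        expected = np.log(marginal(x[0], mu, sigma, lam, tau)) + np.log(
            marginal(x[1], mu_n, sigma_n, lam_n, tau_n)
        )
        assert log_likelihood(x, [1.0], src, TDFSpec()) == pytest.approx(expected, abs=1e-6)

    def test_zero_variance_off_mean_is_minus_infinity(self):
        src = [SourceDistribution("a", (-19.0, 10.0), (0.0, 0.0))]
        with pytest.warns(UserWarning, match="zero mixture variance"):
            val = log_likelihood([-17.0, 11.7], [1.0], src, TDFSpec(1.0, 0.0, 1.7, 0.0))
        assert val == -np.inf


class TestIlr:
    def test_matches_skbio(self, rng):
        from skbio.stats.composition import ilr as sk_ilr
        from skbio.stats.composition import ilr_inv as sk_ilr_inv

        p = rng.dirichlet(np.ones(5), size=10)
        assert ilr(p) == pytest.approx(sk_ilr(p), abs=1e-12)
        theta = rng.normal(size=(10, 4))
        assert ilr_inv(theta) == pytest.approx(sk_ilr_inv(theta), abs=1e-12)

    def test_roundtrip_and_simplex(self, rng):
        theta = rng.normal(size=(50, 3), scale=2)
        p = ilr_inv(theta)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p > 0).all()
        assert ilr(p) == pytest.approx(theta, abs=1e-9)


class TestGelmanRubin:
    def test_same_distribution_long_chains(self, rng):
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_diverged_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 0.01, 500), rng.normal(100, 0.01, 500)])
        assert gelman_rubin(chains) > 10

    def test_equal_split_halves_floor_exactly_one(self, rng):
        half = rng.normal(size=500)
        chain = np.concatenate([half, half])  # split halves identical
        chains = np.stack([chain, chain])
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=1e-12)

    def test_constant_chains_degenerate_to_one(self):
        assert gelman_rubin(np.ones((2, 100))) == 1.0

    def test_never_below_one(self, rng):
        for seed in range(10):
            chains = np.random.default_rng(seed).normal(size=(3, 200))
            assert gelman_rubin(chains) >= 1.0

    def test_input_validation(self):
        with pytest.raises(MixingError):
            gelman_rubin(np.ones(100))
        with pytest.raises(MixingError):
            gelman_rubin(np.ones((2, 5)))


class TestGeweke:
    def test_white_noise_passes_most_of_the_time(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=1000)
            passes += abs(geweke(x)) < 1.96
        assert 88 <= passes <= 100

    def test_step_change_detected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(3, 1, 500)])
        assert abs(geweke(x)) > 1.96

    def test_constant_chain_is_zero(self):
        assert geweke(np.ones(200)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(MixingError, match="too short"):
            geweke(np.ones(50))


@pytest.fixture(scope="module")
def quick_fit(k3_specs, k3_sources):
    scenario = make_k3_scenario(k3_specs, n=20, seed=13)
    consumers, _ = generate_consumers(scenario)
    cfg = MixingConfig(chains=2, iterations=2500, burn_in=1000, thin=5, seed=21)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short runs may flag convergence
        posterior, report = fit_mixing_model(consumers, k3_sources, cfg)
    return consumers, cfg, posterior, report


class TestFit:
    def test_draw_shapes_and_simplex(self, quick_fit):
        consumers, cfg, posterior, report = quick_fit
        n_keep = (cfg.iterations - cfg.burn_in) // cfg.thin
        assert posterior.individual_draws.shape == (2, n_keep, len(consumers), 3)
        assert posterior.group_draws.shape == (2, n_keep, 1, 3)
        assert np.allclose(posterior.individual_draws.sum(-1), 1.0, atol=1e-9)
        assert np.allclose(posterior.group_draws.sum(-1), 1.0, atol=1e-9)
        assert (posterior.individual_draws >= 0).all()

    def test_seeded_determinism(self, k3_specs, k3_sources):
        scenario = make_k3_scenario(k3_specs, n=10, seed=3)
        consumers, _ = generate_consumers(scenario)
        cfg = MixingConfig(chains=2, iterations=600, burn_in=300, thin=3, seed=17)
        a, _ = fit_mixing_model(consumers, k3_sources, cfg)
        b, _ = fit_mixing_model(consumers, k3_sources, cfg)
        assert np.array_equal(a.individual_draws, b.individual_draws)
        assert np.array_equal(a.sigma_draws, b.sigma_draws)

    def test_single_source_posterior_is_point_mass(self, k3_specs):
        scenario = make_k3_scenario(k3_specs, n=5, seed=3)
        consumers, _ = generate_consumers(scenario)
        src = [SourceDistribution("only", (-18.7, 9.3), (0.3, 0.6))]
        posterior, report = fit_mixing_model(consumers, src, MixingConfig(chains=2))
        assert (posterior.individual_draws == 1.0).all()
        assert report.converged

    def test_identical_sources_flagged_non_identifiable(self, k3_specs):
        scenario = make_k3_scenario(k3_specs, n=5, seed=3)
        consumers, _ = generate_consumers(scenario)
        src = [
            SourceDistribution("a", (-18.7, 9.3), (0.3, 0.6)),
            SourceDistribution("b", (-18.7, 9.3), (0.3, 0.6)),
        ]
        cfg = MixingConfig(chains=2, iterations=400, burn_in=200, thin=2, seed=1)
        with pytest.warns(UserWarning, match="identical tracer distributions"):
            posterior, _ = fit_mixing_model(consumers, src, cfg)
        assert posterior.non_identifiable_pairs == [("a", "b")]

    def test_missing_columns_rejected(self, k3_sources):
        with pytest.raises(MixingError, match="column"):
            fit_mixing_model(pd.DataFrame({"d13C": [1.0]}), k3_sources, MixingConfig())

    def test_config_validation(self):
        with pytest.raises(MixingError):
            MixingConfig(iterations=100, burn_in=100)
        with pytest.raises(MixingError):
            MixingConfig(chains=1)
        with pytest.raises(MixingError):
            MixingConfig(prior_alpha=(1.0, 0.0))
        preset = MixingConfig(preset="extreme")
        assert preset.iterations == 3_000_000

    def test_monte_carlo_error_shrinks_with_iterations(self, k3_specs, k3_sources):
        # doubling the retained draws should shrink the spread of repeated
        # posterior-mean estimates by roughly sqrt(2)
        scenario = make_k3_scenario(k3_specs, n=15, seed=5)
        consumers, _ = generate_consumers(scenario)

        def spread(iters):
            means = []
            for seed in range(6):
                cfg = MixingConfig(
                    chains=2, iterations=iters, burn_in=500, thin=2, seed=100 + seed
                )
                post, _ = fit_mixing_model(consumers, k3_sources, cfg)
                means.append(post.flat_group()[:, 0, 0].mean())
            return np.std(means)

        s1, s2 = spread(1500), spread(4500)
        assert s2 < s1 * 1.1  # allow noise; the trend must not reverse


class TestSummaries:
    def test_degenerate_posterior_collapses(self, k3_specs, k3_sources):
        scenario = make_k3_scenario(k3_specs, n=4, seed=3)
        consumers, _ = generate_consumers(scenario)
        src = [SourceDistribution("only", (-18.7, 9.3), (0.3, 0.6))]
        posterior, _ = fit_mixing_model(consumers, src, MixingConfig(chains=2))
        out = summarize_posterior(posterior, by="individual")
        assert (out["sd"] == 0.0).all()
        assert (out["ci_2.5"] == out["ci_97.5"]).all()

    def test_mean_rows_sum_to_one(self, k3_specs, k3_sources):
        scenario = make_k3_scenario(k3_specs, n=8, seed=9)
        consumers, _ = generate_consumers(scenario)
        cfg = MixingConfig(chains=2, iterations=600, burn_in=300, thin=3, seed=2)
        posterior, _ = fit_mixing_model(consumers, k3_sources, cfg)
        for by in ("individual", "group"):
            out = summarize_posterior(posterior, by=by)
            sums = out.groupby("unit_id")["mean"].sum()
            assert np.allclose(sums, 1.0, atol=1e-6)
        per = summarize_posterior(
            posterior, by="period", period_map={i: "pre" for i in posterior.individual_ids}
        )
        assert per["mean"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_unknown_grouping_rejected(self, k3_specs, k3_sources):
        scenario = make_k3_scenario(k3_specs, n=4, seed=3)
        consumers, _ = generate_consumers(scenario)
        src = [SourceDistribution("only", (-18.7, 9.3), (0.3, 0.6))]
        posterior, _ = fit_mixing_model(consumers, src, MixingConfig(chains=2))
        with pytest.raises(MixingError):
            summarize_posterior(posterior, by="cohort")

    def test_convergence_report_frame(self):
        rep = ConvergenceReport(
            rhat={"a": 1.01, "b": 1.5}, geweke_z={"a": np.array([0.2]), "b": np.array([3.0])}
        )
        frame = rep.to_frame()
        assert not rep.rhat_ok
        assert set(frame["parameter"]) == {"a", "b"}
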