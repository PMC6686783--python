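"""Nighttime E0 fit, likelihoods, DE-MC sampler and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cospart.forward_models import LightParams, RespirationParams, reco_lloyd_taylor
from cospart.inversion import (
    FPLikelihood,
    FPPlusLikelihood,
    PriorSpec,
    UniformPrior,
    default_priors,
    fit_e0_nighttime,
    fit_fpplus,
    gelman_rubin,
    loglik_fp,
    loglik_fpplus,
    posterior_summary,
    sample_posterior,
    PosteriorChains,
)
from cospart.synthetic_campaign import preset, simulate_meteo, simulate_observations, simulate_truth


def _night_frame(rb, e0, n=500, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t_air = rng.uniform(2.0, 15.0, n)
    reco = reco_lloyd_taylor(RespirationParams(rb, e0), t_air)
    return pd.DataFrame(
        {"par": np.zeros(n), "t_air": t_air, "nee": reco + rng.normal(0, sigma, n)}
    )


class TestNighttimeE0:
    def test_noise_free_recovery(self):
        e0, rb = fit_e0_nighttime(_night_frame(3.0, 150.0))
        assert e0 == pytest.approx(150.0, rel=1e-4)
        assert rb == pytest.approx(3.0, rel=1e-4)

    def test_noisy_recovery_within_band(self):
        """E0 from 500 noisy nights stays within +-15 of truth (10 replicates)."""
        for rep in range(10):
            e0, _ = fit_e0_nighttime(_night_frame(3.0, 150.0, sigma=0.5, seed=100 + rep))
            assert abs(e0 - 150.0) < 15.0

    def test_isothermal_nights_unidentifiable(self):
        df = _night_frame(3.0, 150.0)
        df["t_air"] = 10.0
        with pytest.raises(ValueError, match="isothermal"):
            fit_e0_nighttime(df)

    def test_too_few_nights(self):
        with pytest.raises(ValueError, match="nighttime"):
            fit_e0_nighttime(_night_frame(3.0, 150.0, n=10))


def _toy_daytime(n=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "par": rng.uniform(50, 1500, n),
            "t_air": rng.uniform(10, 25, n),
            "nee": rng.normal(-10, 5, n),
            "chi_co2": np.full(n, 400.0),
            "chi_cos": np.full(n, 500.0),
            "f_cos_canopy": rng.normal(-30, 10, n),
        }
    )


class TestLikelihoods:
    def test_fp_matches_hand_summed_gaussian(self):
        """FP log-likelihood equals the normal log-density summed by hand."""
        day = _toy_daytime()
        e0, theta = 150.0, np.array([0.05, 20.0, 2.0, 1.5])
        lp, rp = LightParams(0.05, 20.0), RespirationParams(2.0, e0)
        mu = reco_lloyd_taylor(rp, day["t_air"].to_numpy()) - (
            0.05 * 20.0 * day["par"].to_numpy() / (0.05 * day["par"].to_numpy() + 20.0)
        )
        hand = stats.norm.logpdf(day["nee"].to_numpy(), mu, 1.5).sum()
        assert loglik_fp(theta, e0, day) == pytest.approx(hand, rel=1e-12)

    def test_fpplus_matches_two_stream_sum(self):
        day = _toy_daytime()
        e0 = 150.0
        theta = np.array([0.05, 20.0, 2.0, 1.7, 30.0, 1.5, 3.0])
        mu_nee = reco_lloyd_taylor(RespirationParams(2.0, e0), day["t_air"].to_numpy()) - (
            0.05 * 20.0 * day["par"] / (0.05 * day["par"] + 20.0)
        )
        gpp = 0.05 * 20.0 * day["par"] / (0.05 * day["par"] + 20.0)
        lru = 1.7 * np.exp(30.0 / day["par"])
        ratio = day["chi_co2"] * 1e-6 / (day["chi_cos"] * 1e-12)
        mu_cos = gpp * lru * 1e6 / ratio
        hand = (
            stats.norm.logpdf(day["nee"], mu_nee, 1.5).sum()
            + stats.norm.logpdf(-day["f_cos_canopy"], mu_cos, 3.0).sum()
        )
        assert loglik_fpplus(theta, e0, day) == pytest.approx(hand, rel=1e-12)

    def test_truth_residuals_standardized(self):
        """At generator truth, per-stream standardized residuals have unit variance."""
        scen = preset("GRA", seed=21, n_days=70)
        truth = simulate_truth(scen, simulate_meteo(scen))
        obs = simulate_observations(truth, (1.0, 3.0), seed=22)
        obs["f_cos_canopy"] = obs["fcos_eco"] - obs["f_soil_true"]
        day = obs[obs["par"] > 10.0]
        assert len(day) >= 2000
        resid_nee = (day["nee"] - day["nee_true"]) / 1.0
        resid_cos = (-day["f_cos_canopy"] - (-day["f_cos_canopy_true"])) / 3.0
        assert np.var(resid_nee) == pytest.approx(1.0, rel=0.05)
        assert np.var(resid_cos) == pytest.approx(1.0, rel=0.05)

    def test_uninformative_cos_stream_reduces_to_fp(self):
        """With sigma_COS huge, FP+ likelihood differences match FP differences."""
        day = _toy_daytime(n=40, seed=3)
        e0 = 120.0
        t1 = np.array([0.05, 20.0, 2.0, 1.7, 30.0, 1.5, 1e9])
        t2 = np.array([0.07, 25.0, 3.0, 1.7, 30.0, 1.5, 1e9])
        d_plus = loglik_fpplus(t1, e0, day) - loglik_fpplus(t2, e0, day)
        d_fp = loglik_fp(t1[[0, 1, 2, 5]], e0, day) - loglik_fp(t2[[0, 1, 2, 5]], e0, day)
        assert d_plus == pytest.approx(d_fp, abs=1e-6)

    def test_empty_daytime_rejected(self):
        with pytest.raises(ValueError):
            FPLikelihood(_toy_daytime(0), 150.0)


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        rng = np.random.default_rng(0)
        one = rng.normal(0, 1, (1, 10_000, 2))
        chains = np.repeat(one, 4, axis=0)
        assert np.allclose(gelman_rubin(chains), 1.0, atol=1e-3)

    def test_independent_draws_near_unity(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(0, 1, (4, 10_000, 1))
        assert float(gelman_rubin(chains)[0]) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(0, 1, (1, 5000, 1))
        c2 = rng.normal(10, 1, (1, 5000, 1))
        # closed form: W = 1, B/n = 50 -> R-hat ~ sqrt(51) ~ 7.1
        assert float(gelman_rubin(np.concatenate([c1, c2]))[0]) > 5.0

    def test_matches_arviz_on_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(0, 1, (4, 5000, 1))
        ours = float(gelman_rubin(chains)[0])
        theirs = float(az.rhat(az.convert_to_dataset(chains[:, :, 0])).x)
        assert ours == pytest.approx(theirs, abs=0.01)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 1)))


class _GaussTarget:
    """Analytic 2-D Gaussian log-density (independent components)."""

    param_names = ("x", "y")

    def __init__(self, mean, sd):
        self.mean = np.asarray(mean)
        self.sd = np.asarray(sd)

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        z = (theta - self.mean) / self.sd
        return -0.5 * np.sum(z**2, axis=1)


class TestSampler:
    def test_gaussian_target_moments(self):
        """Moments of an analytic 2-D Gaussian recovered from ~10k draws."""
        target = _GaussTarget([2.0, -3.0], [1.0, 2.0])
        priors = PriorSpec({"x": UniformPrior(-20, 20), "y": UniformPrior(-30, 30)})
        chains = sample_posterior(target, priors, n_chains=8, n_iter=4000, seed=5,
                                  retain=10_000)
        draws = chains.retained()
        assert chains.converged
        assert np.allclose(draws.mean(axis=0), [2.0, -3.0], atol=0.15)
        assert np.allclose(draws.std(axis=0), [1.0, 2.0], rtol=0.1)

    def test_flat_likelihood_recovers_uniform_prior(self):
        flat = lambda theta: np.zeros(np.atleast_2d(theta).shape[0])  # noqa: E731
        priors = PriorSpec({"u": UniformPrior(0.0, 1.0)})
        chains = sample_posterior(flat, priors, n_chains=6, n_iter=4000, seed=6,
                                  retain=5000, init="prior")
        draws = chains.retained()[:, 0]
        ks = stats.kstest(draws[:: max(1, len(draws) // 500)], "uniform")
        assert ks.pvalue > 0.01

    def test_identical_seeds_identical_chains(self):
        target = _GaussTarget([0.0, 0.0], [1.0, 1.0])
        priors = PriorSpec({"x": UniformPrior(-10, 10), "y": UniformPrior(-10, 10)})
        kw = dict(n_chains=6, n_iter=800, seed=9, retain=600)
        c1 = sample_posterior(target, priors, **kw)
        c2 = sample_posterior(target, priors, **kw)
        assert np.array_equal(c1.samples, c2.samples)

    def test_unconverged_flagged_not_silent(self):
        # bimodal far-separated target cannot converge in a short run
        def bimodal(theta):
            theta = np.atleast_2d(theta)
            a = -0.5 * ((theta[:, 0] + 50) / 0.1) ** 2
            b = -0.5 * ((theta[:, 0] - 50) / 0.1) ** 2
            return np.logaddexp(a, b)

        priors = PriorSpec({"x": UniformPrior(-100, 100)})
        with pytest.warns(UserWarning, match="did not converge"):
            chains = sample_posterior(bimodal, priors, n_chains=6, n_iter=600,
                                      seed=3, retain=500, init="prior")
        assert not chains.converged

    def test_too_few_chains_rejected(self):
        priors = PriorSpec({"x": UniformPrior(0, 1), "y": UniformPrior(0, 1),
                            "z": UniformPrior(0, 1)})
        with pytest.raises(ValueError, match="chains"):
            sample_posterior(_GaussTarget([0, 0], [1, 1]), priors, n_chains=3)


class TestPosteriorSummary:
    def _chains_from(self, draws, names=("x",)):
        c, n, d = draws.shape
        lp = -0.5 * np.sum(draws**2, axis=2)
        return PosteriorChains(
            samples=draws, loglik=lp, logpost=lp, param_names=names, burn_in=0,
            seed=0, acceptance_rate=0.5, rhat=np.ones(d), converged=True,
        )

    def test_normal_quantiles(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(0, 1, (4, 25_000, 1))
        res = posterior_summary(self._chains_from(draws))
        row = res.table.loc["x"]
        assert row["ci_lo"] == pytest.approx(-1.96, abs=0.04)
        assert row["ci_hi"] == pytest.approx(1.96, abs=0.04)
        assert row["median"] == pytest.approx(row["mean"], abs=0.02)

    def test_map_near_mode(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(0, 1, (4, 25_000, 1))
        res = posterior_summary(self._chains_from(draws))
        assert abs(res.map_params["x"]) < 0.05

    def test_unconverged_flag_carried(self):
        rng = np.random.default_rng(6)
        draws = rng.normal(0, 1, (2, 100, 1))
        ch = self._chains_from(draws)
        ch.converged = False
        res = posterior_summary(ch)
        assert not res.converged
        assert "UNCONVERGED" in res.to_text()


class TestPriorSensitivity:
    def test_iota_robust_to_prior_choice(self, gra_campaign):
        """Informative vs uniform iota prior moves the estimate little vs its CI."""
        _, flux, _ = gra_campaign
        f_inf = fit_fpplus(flux, iota_prior="informative", seed=13)
        f_uni = fit_fpplus(flux, iota_prior="uniform", seed=14)
        med_i = f_inf.result.table.loc["iota", "median"]
        med_u = f_uni.result.table.loc["iota", "median"]
        ci = f_inf.result.table.loc["iota"]
        assert abs(med_i - med_u) < (ci["ci_hi"] - ci["ci_lo"])
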