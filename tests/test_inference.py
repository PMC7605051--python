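import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from stereocoupling.inference import (
    MCMCConfig,
    PriorSpec,
    fit_cohort,
    fit_hierarchical,
    hdi,
    log_likelihood,
    sample_posterior,
    split_rhat,
)
from stereocoupling.observers import ObserverParams, psychometric_prob, simulate_baseline_subject
from stereocoupling.stimulus import baseline_trial_schedule


def _subject(theta, omega, repeats=20, seed=42, sim_seed=77):
    sched = baseline_trial_schedule(repeats, [0.0, 2.3, 4.6], seed=seed)
    return simulate_baseline_subject(ObserverParams(theta, omega), sched, seed=sim_seed)


class TestLogLikelihood:
    def test_single_trial_at_theta(self):
        df = pd.DataFrame(
            [("s", "baseline", 0, 2.0, "convex", "convex", None)],
            columns=["subject_id", "experiment", "trial_index", "disparity_arcmin",
                     "condition", "response", "coupled_correct"],
        )
        assert log_likelihood(2.0, 5.0, df) == pytest.approx(math.log(0.5))

    def test_matches_brute_force_product(self):
        df = _subject(1.0, 8.0, repeats=2)
        obs = ObserverParams(1.0, 8.0)
        brute = 0.0
        for _, row in df.iterrows():
            p = psychometric_prob(obs, row["disparity_arcmin"])
            brute += math.log(p if row["response"] == "convex" else 1 - p)
        assert log_likelihood(1.0, 8.0, df) == pytest.approx(brute, abs=1e-10)

    def test_order_invariance(self):
        df = _subject(0.0, 5.0, repeats=3)
        shuffled = df.sample(frac=1.0, random_state=0)
        assert log_likelihood(0.5, 4.0, df) == pytest.approx(log_likelihood(0.5, 4.0, shuffled))

    def test_rejects_coupling_records_and_bad_omega(self):
        df = _subject(0.0, 5.0, repeats=1)
        bad = df.copy()
        bad.loc[bad.index[0], "experiment"] = "coupling"
        with pytest.raises(ValueError):
            log_likelihood(0.0, 5.0, bad)
        with pytest.raises(ValueError):
            log_likelihood(0.0, -5.0, df)


class TestHDI:
    def test_degenerate_and_errors(self):
        assert hdi(np.full(10, 3.2)) == (3.2, 3.2)
        with pytest.raises(ValueError):
            hdi(np.array([1.0]))
        with pytest.raises(ValueError):
            hdi(np.arange(10), mass=1.5)

    def test_uniform_width(self, rng):
        draws = rng.uniform(0, 1, 100_000)
        lo, hi = hdi(draws, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_quantiles(self, rng):
        draws = rng.standard_normal(200_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_agrees_with_arviz(self, rng):
        import arviz as az

        draws = rng.gamma(2.0, 1.5, 20_000)
        ours = hdi(draws, 0.95)
        theirs = az.hdi(draws, hdi_prob=0.95)
        assert ours[0] == pytest.approx(theirs[0], abs=0.02)
        assert ours[1] == pytest.approx(theirs[1], abs=0.02)


def test_split_rhat_agrees_with_arviz(rng):
    import arviz as az

    mixed = rng.standard_normal((4, 2000))
    sticky = mixed + np.array([0.0, 0.5, 1.0, 1.5])[:, None]
    for chains in (mixed, sticky):
        assert split_rhat(chains) == pytest.approx(float(az.rhat(chains)), abs=0.01)


class TestSamplePosterior:
    def test_deterministic_given_seed(self, fast_mcmc):
        df = _subject(0.0, 5.0)
        a = sample_posterior(df, PriorSpec(), fast_mcmc)
        b = sample_posterior(df, PriorSpec(), fast_mcmc)
        assert np.array_equal(a.theta, b.theta) and np.array_equal(a.omega, b.omega)

    def test_no_data_returns_prior(self):
        cfg = MCMCConfig(n_chains=4, n_samples=25_000, n_burnin=10, seed=3)
        empty = pd.DataFrame(columns=["subject_id", "experiment", "disparity_arcmin", "response"])
        post = sample_posterior(empty, PriorSpec(), cfg, subject_id="none")
        assert post.prior_only
        # theta quantiles match the N(0, 20) prior to ~1%
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(post.theta, q) == pytest.approx(
                stats.norm.ppf(q, 0, 20), abs=0.6
            )
        # steepness 1/omega is uniform under the default prior
        s = np.sort(1.0 / post.omega)
        grid = np.linspace(1 / 500 + 1e-6, 2 - 1e-6, 50)
        ecdf = np.searchsorted(s, grid) / s.size
        cdf = (grid - 1 / 500) / (2 - 1 / 500)
        assert np.max(np.abs(ecdf - cdf)) < 0.01

    def test_posterior_mean_matches_grid_oracle(self):
        # independent oracle: dense numerical integration of the same posterior
        df = _subject(1.5, 6.0, sim_seed=5)
        priors = PriorSpec()
        cfg = MCMCConfig(n_chains=4, n_samples=4000, n_burnin=1000, seed=11)
        post = sample_posterior(df, priors, cfg)

        theta_g = np.linspace(-15, 15, 301)
        logw_g = np.linspace(math.log(0.5), math.log(500), 401)
        lp = priors.log_prior(theta_g[:, None], logw_g[None, :])
        from stereocoupling.inference import _level_counts, _loglik_counts

        d, n, k = _level_counts(df)
        ll = _loglik_counts(
            np.repeat(theta_g, logw_g.size), np.tile(logw_g, theta_g.size), d, n, k
        ).reshape(theta_g.size, logw_g.size)
        w = np.exp(lp + ll - logsumexp(lp + ll))
        assert post.theta.mean() == pytest.approx(float((w.sum(1) * theta_g).sum()), abs=0.15)
        assert np.log(post.omega).mean() == pytest.approx(float((w.sum(0) * logw_g).sum()), abs=0.1)

    def test_recovery_single_replicate(self):
        df = _subject(1.0, 5.0, repeats=200)
        post = sample_posterior(df, PriorSpec(), MCMCConfig(seed=13))
        assert post.hdi_95["theta"][0] <= 1.0 <= post.hdi_95["theta"][1]
        assert post.hdi_95["omega"][0] <= 5.0 <= post.hdi_95["omega"][1]
        assert post.converged

    def test_separability_of_regimes(self, fast_mcmc):
        steep = sample_posterior(_subject(0.0, 5.0), PriorSpec(), fast_mcmc)
        flat = sample_posterior(_subject(0.0, 200.0, sim_seed=8), PriorSpec(), fast_mcmc)
        assert (steep.omega > 100).mean() < 0.05
        assert (flat.omega < 10).mean() < 0.05

    def test_hdi_width_shrinks_with_data(self):
        cfg = MCMCConfig(n_chains=2, n_samples=3000, n_burnin=1000, seed=21)
        small = sample_posterior(_subject(0.0, 5.0, repeats=20), PriorSpec(), cfg)
        large = sample_posterior(_subject(0.0, 5.0, repeats=200), PriorSpec(), cfg)
        for par in ("theta", "omega"):
            w_small = small.hdi_95[par][1] - small.hdi_95[par][0]
            w_large = large.hdi_95[par][1] - large.hdi_95[par][0]
            assert w_large <= w_small

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_samples=0)
        with pytest.raises(ValueError):
            PriorSpec(omega_lo=5.0, omega_hi=1.0)
        with pytest.raises(ValueError):
            PriorSpec(omega_prior="cauchy")


class TestHierarchical:
    def test_group_mean_recovery(self, rng):
        sched = baseline_trial_schedule(20, [0.0, 2.3, 4.6], seed=5)
        frames = [
            simulate_baseline_subject(
                ObserverParams(rng.normal(2, 1), 5.0), sched, seed=100 + i, subject_id=f"S{i}"
            )
            for i in range(10)
        ]
        df = pd.concat(frames, ignore_index=True)
        res = fit_hierarchical(df, PriorSpec(), MCMCConfig(n_chains=2, n_samples=3000, n_burnin=1000, seed=9))
        lo, hi = hdi(res["group_level"]["mu_theta"], 0.95)
        assert lo <= 2.0 <= hi
        assert max(res["group_rhat"].values()) < 1.1

    def test_identical_subjects_shrink_sigma(self):
        sched = baseline_trial_schedule(20, [0.0, 2.3, 4.6], seed=5)
        one = simulate_baseline_subject(ObserverParams(1.0, 5.0), sched, seed=3)
        frames = [one.assign(subject_id=f"S{i}") for i in range(6)]
        same = pd.concat(frames, ignore_index=True)
        cfg = MCMCConfig(n_chains=2, n_samples=2000, n_burnin=800, seed=4)
        res_same = fit_hierarchical(same, PriorSpec(), cfg)

        spread = pd.concat(
            [
                simulate_baseline_subject(
                    ObserverParams(theta, 5.0), sched, seed=30 + i, subject_id=f"S{i}"
                )
                for i, theta in enumerate([-12, -7, -2, 2, 7, 12])
            ],
            ignore_index=True,
        )
        res_spread = fit_hierarchical(spread, PriorSpec(), cfg)
        assert (
            np.median(res_same["group_level"]["sigma_theta"])
            < np.median(res_spread["group_level"]["sigma_theta"]) / 2
        )

    def test_shrinkage_small_for_informative_data(self):
        sched = baseline_trial_schedule(200, [0.0, 2.3, 4.6], seed=5)
        frames = [
            simulate_baseline_subject(ObserverParams(t, 5.0), sched, seed=50 + i, subject_id=f"S{i}")
            for i, t in enumerate([0.0, 1.0, 2.0])
        ]
        df = pd.concat(frames, ignore_index=True)
        cfg = MCMCConfig(n_chains=2, n_samples=2500, n_burnin=1000, seed=6)
        hier = fit_hierarchical(df, PriorSpec(), cfg)
        flat = fit_cohort(df, PriorSpec(), cfg)
        for sid in flat:
            assert hier["subjects"][sid].theta.mean() == pytest.approx(
                flat[sid].theta.mean(), abs=1.0
            )

    def test_single_subject_falls_back(self):
        df = _subject(0.0, 5.0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = fit_hierarchical(df, PriorSpec(), MCMCConfig(n_chains=2, n_samples=500, n_burnin=200, seed=2))
        assert res["group_level"] is None
        assert any("hierarchical" in str(w.message) for w in caught)
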