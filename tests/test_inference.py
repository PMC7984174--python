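"""Likelihood construction, MCMC fitting, convergence diagnostics, prediction."""

import numpy as np
import pytest
from scipy import stats

from stagessm.inference import (
    MCMCConfig,
    build_likelihood,
    fit,
    gelman_rubin,
    posterior_summary,
    predict_vital_rate,
    predictive_checks,
)
from stagessm.model_core import STAGES, cv_to_logvar
from stagessm.synthetic_data import StudyConfig, generate_dataset


def _true_theta(ds, model):
    """Assemble the generating parameter/residual vector for a dataset."""
    theta = np.zeros(model.ndim)
    for p, sl in model._coef_slices.items():
        theta[sl] = ds.params.coef(p)
    theta[model._sigmaP_slice] = [ds.params.sigmaP[p] for p in ("R", "PL", "J", "SA")]
    theta[model._psi_slice] = [ds.obs_params.psi[s] for s in model.psi_stages]
    if model.scenario == 3:
        theta[model._sigmaO_slice] = 0.5
    # standardized residuals implied by the realized vital rates
    link = np.empty((4, ds.config.T))
    link[0] = np.log(ds.trajectory.rho)
    link[1:] = np.log(ds.trajectory.phi / (1 - ds.trajectory.phi))
    z = np.empty((4, ds.config.T))
    for i, p in enumerate(("R", "PL", "J", "SA")):
        mu = ds.covariates.design(p) @ ds.params.coef(p)
        z[i] = (link[i] - mu) / ds.params.sigmaP[p]
    theta[model.n_free :] = z.ravel()
    return theta


class TestBuildLikelihood:
    def test_scenario1_matches_lognormal_density(self, small_dataset):
        ds = small_dataset
        m = build_likelihood(ds.observed, ds.covariates, scenario=1, nA0=ds.config.nA0)
        theta = _true_theta(ds, m)
        got = m.log_likelihood(theta[None, :])[0]
        # independent recomputation via scipy at the same latent states
        free, z = m._unpack(theta[None, :])
        log_n, _ = m.log_states(free, z)
        psi = ds.obs_params.psi_matrix(ds.config.T)
        total = 0.0
        for i in range(4):
            for t in range(ds.config.T):
                lv = cv_to_logvar(ds.observed.cv_ex[i, t])
                median = psi[i, t] * np.exp(log_n[0, i, t]) / np.sqrt(
                    ds.observed.cv_ex[i, t] ** 2 + 1
                )
                total += stats.lognorm.logpdf(
                    ds.observed.nhat[i, t], s=np.sqrt(lv), scale=median
                )
        assert got == pytest.approx(total, rel=1e-10)

    def test_scenario3_adds_four_noise_parameters(self, small_dataset):
        ds = small_dataset
        m1 = build_likelihood(ds.observed, ds.covariates, scenario=1, nA0=ds.config.nA0)
        m3 = build_likelihood(ds.observed, ds.covariates, scenario=3, nA0=ds.config.nA0)
        assert m3.n_free - m1.n_free == 4
        assert [n for n in m3.param_names if n.startswith("sigmaO")] == [
            f"sigmaO_{s}" for s in STAGES
        ]

    def test_scenario2_reduces_to_scenario1_at_true_state(self, small_dataset):
        ds = small_dataset
        psi = ds.obs_params.psi_matrix(ds.config.T)
        var_ex = (ds.true_cv * psi * ds.trajectory.n) ** 2
        m2 = build_likelihood(
            ds.observed, ds.covariates, scenario=2, nA0=ds.config.nA0, var_ex=var_ex
        )
        theta = _true_theta(ds, m2)
        free, z = m2._unpack(theta[None, :])
        log_n, _ = m2.log_states(free, z)
        lv2 = m2._obs_logvar(free, log_n, m2._log_psi(free))[0]
        assert np.allclose(lv2, cv_to_logvar(ds.true_cv), rtol=1e-10)

    def test_scenario1_requires_external_cv(self, small_dataset):
        ds = small_dataset
        from stagessm.model_core import IndexDataset

        bare = IndexDataset(nhat=ds.observed.nhat, mask=ds.observed.mask)
        with pytest.raises(ValueError, match="external CV"):
            build_likelihood(bare, ds.covariates, scenario=1, nA0=ds.config.nA0)

    def test_unknown_scenario_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError, match="scenario"):
            build_likelihood(ds.observed, ds.covariates, scenario=4, nA0=ds.config.nA0)

    def test_likelihood_at_truth_beats_perturbed_states(self, small_dataset):
        ds = small_dataset
        m = build_likelihood(ds.observed, ds.covariates, scenario=1, nA0=ds.config.nA0)
        theta = _true_theta(ds, m)
        base = m.log_prob_single(theta)
        rng = np.random.default_rng(8)
        for _ in range(20):
            pert = theta.copy()
            pert[m.n_free :] += rng.normal(0, 0.7, m.ndim - m.n_free)
            assert m.log_prob_single(pert) < base


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        chain = rng.standard_normal(100_000)
        r = gelman_rubin(np.stack([chain, chain]), split=False)
        assert r <= 1.0 + 1e-12
        assert r == pytest.approx(1.0, abs=1e-4)

    def test_separated_chains_flagged(self, rng):
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000) + 10.0
        assert gelman_rubin(np.stack([a, b])) > 5.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="two chains"):
            gelman_rubin(rng.standard_normal((1, 100)))

    def test_matches_arviz_reference(self, rng):
        import arviz as az

        draws = rng.standard_normal((4, 500)) + 0.1 * np.arange(500)
        mine = gelman_rubin(draws, split=False)
        ref = float(az.rhat(draws, method="identity"))
        assert mine == pytest.approx(ref, rel=1e-6)
        # splitting must detect the shared within-chain trend
        assert gelman_rubin(draws, split=True) > 1.5


class TestFit:
    def test_degenerate_data_recovery(self):
        # near-noise-free data: posterior concentrates on the generating values
        cfg = StudyConfig(
            T=10,
            sigmaP={"R": 0.01, "PL": 0.01, "J": 0.01, "SA": 0.01},
            cv_range=(0.01, 0.0101),
            seed=21,
        )
        ds = generate_dataset(cfg)
        m = build_likelihood(ds.observed, ds.covariates, scenario=1, nA0=cfg.nA0)
        res = fit(m, MCMCConfig(n_steps=2000, seed=4))
        for p in ("R", "PL", "J", "SA"):
            for j, truth in enumerate(cfg.coefs[p]):
                name = f"{ {'R':'zeta','PL':'beta','J':'eta','SA':'gamma'}[p] }{j}".replace(" ", "")
                mean, sd = res.posterior_mean(name), res.posterior_sd(name)
                assert abs(mean - truth) < max(2 * sd, 0.05), name
        for s, truth in (("J", 0.5), ("SA", 0.2)):
            mean, sd = res.posterior_mean(f"psi_{s}"), res.posterior_sd(f"psi_{s}")
            assert abs(mean - truth) < max(2 * sd, 0.02)

    def test_bias_direction_recovered(self, small_fit):
        # data generated with psi < 1: posterior mass tilts below 1 even at
        # this short (8-cohort) series; the strongly biased sub-adult stage
        # (psi_SA = 0.2) is decisively below 1
        assert np.mean(small_fit.param("psi_SA") < 1.0) > 0.95
        assert np.mean(small_fit.param("psi_J") < 1.0) > 0.55

    def test_doubling_iterations_stable_means(self, small_dataset):
        ds = small_dataset
        m = build_likelihood(ds.observed, ds.covariates, scenario=1, nA0=ds.config.nA0)
        r1 = fit(m, MCMCConfig(n_steps=1500, seed=5))
        r2 = fit(m, MCMCConfig(n_steps=3000, seed=6))
        for name in ("psi_J", "psi_SA", "zeta1"):
            sd = max(r1.posterior_sd(name), r2.posterior_sd(name))
            assert abs(r1.posterior_mean(name) - r2.posterior_mean(name)) < 0.75 * sd

    def test_latent_states_positive_and_shapes(self, small_fit):
        assert np.isfinite(small_fit.latent_log_n).all()
        assert small_fit.draws.shape[2] == len(small_fit.param_names)
        assert all(np.isfinite(v) for v in small_fit.rhat.values())


class TestPosteriorSummary:
    def test_moments_and_quantiles_definition(self, small_fit):
        tab = posterior_summary(small_fit, include_latent=False)
        v = small_fit.param("psi_J")
        row = tab.loc["psi_J"]
        assert row["mean"] == pytest.approx(v.mean())
        assert row["q2.5"] == pytest.approx(np.quantile(v, 0.025))
        assert row["q75"] == pytest.approx(np.quantile(v, 0.75))

    def test_latent_state_summaries_positive(self, small_fit):
        tab = posterior_summary(small_fit, include_latent=True)
        latents = tab[tab.index.str.startswith("n_")]
        assert len(latents) == 4 * small_fit.model.T
        assert (latents["mean"] > 0).all() and (latents["q2.5"] > 0).all()


class TestPredictVitalRate:
    def test_bands_widen_with_parameter_uncertainty(self, small_fit):
        grid = np.column_stack([np.ones(9), np.linspace(-2, 2, 9), np.zeros(9)])
        with_u = predict_vital_rate(small_fit, "PL", grid, include_param_uncertainty=True,
                                    n_draws=20000, seed=1)
        without = predict_vital_rate(small_fit, "PL", grid, include_param_uncertainty=False,
                                     n_draws=20000, seed=1)
        assert (with_u["hi95"] - with_u["lo95"] >= without["hi95"] - without["lo95"] - 0.02).all()

    def test_median_matches_direct_monte_carlo(self, small_fit):
        grid = np.array([[1.0, 0.5, 0.0]])
        out = predict_vital_rate(small_fit, "J", grid, n_draws=100_000, seed=2)
        # independent brute force from the raw posterior draws
        rng = np.random.default_rng(99)
        flat = small_fit.flat
        idx = rng.integers(0, flat.shape[0], 100_000)
        sl = small_fit.model._coef_slices["J"]
        lp = flat[idx, sl] @ grid[0]
        sig = flat[idx, small_fit.model._sigmaP_slice][:, 2]
        rate = 1 / (1 + np.exp(-(lp + sig * rng.standard_normal(len(idx)))))
        assert out["median"].iloc[0] == pytest.approx(np.median(rate), abs=0.01)

    def test_grid_mismatch_rejected(self, small_fit):
        with pytest.raises(ValueError, match="grid"):
            predict_vital_rate(small_fit, "J", np.ones((3, 5)))


class TestPredictiveChecks:
    def test_residuals_standard_normal_for_self_simulated_data(self, small_fit):
        from stagessm.model_core import IndexDataset

        rng = np.random.default_rng(11)
        _, reps = predictive_checks(small_fit, seed=3)
        n_pass = 0
        n_rep = 10
        for k in range(n_rep):
            sim = IndexDataset(nhat=reps[rng.integers(0, reps.shape[0])],
                               mask=small_fit.model.mask)
            resid, _ = predictive_checks(small_fit, data=sim, seed=100 + k)
            r = resid[np.isfinite(resid)]
            n_pass += stats.normaltest(r).pvalue > 0.01
        assert n_pass >= 8

    def test_outlier_cell_flagged(self, small_fit):
        from stagessm.model_core import IndexDataset

        ds = small_fit.model.data
        nhat = ds.nhat.copy()
        nhat[1, 3] *= 10.0
        spiked = IndexDataset(nhat=nhat, cv_ex=ds.cv_ex, mask=ds.mask)
        resid, _ = predictive_checks(small_fit, data=spiked, seed=4)
        assert resid[1, 3] > 2.5
        assert resid[1, 3] == np.nanmax(resid)

    def test_replicate_indices_positive(self, small_fit):
        _, reps = predictive_checks(small_fit, seed=5)
        assert (reps > 0).all()
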