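"""State/observation kernels and the lognormal moment identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stagessm.model_core import (
    STAGES,
    CovariateSet,
    ObservationParams,
    PopulationTrajectory,
    VitalRateParams,
    cv_to_logvar,
    draw_vital_rates,
    index_moments,
    logvar_to_cv,
    observe,
    propagate_states,
)


def _params(sigma=0.0, intercepts=(0.7, 0.0, 0.0, 0.0)):
    return VitalRateParams(
        zeta=[intercepts[0]], beta=[intercepts[1]], eta=[intercepts[2]],
        gamma=[intercepts[3]], sigmaP={"R": sigma, "PL": sigma, "J": sigma, "SA": sigma},
    )


def _intercept_design(T):
    ones = np.ones((T, 1))
    return CovariateSet(xR=ones, xPL=ones, xJ=ones, xSA=ones)


class TestDrawVitalRates:
    def test_zero_noise_degeneracy(self):
        rho, phi = draw_vital_rates(_params(), _intercept_design(5), seed=0)
        assert np.allclose(rho, np.exp(0.7))
        assert np.allclose(phi, 0.5)  # logit(0.5) = 0

    def test_monte_carlo_moments_of_log_recruitment(self):
        # sigmaP_R = 0.5 around a unit log-mean: check Normal moments at 1e6 draws
        T = 1_000_000
        cov = _intercept_design(T)
        p = VitalRateParams(zeta=[1.0], beta=[0.0], eta=[0.0], gamma=[0.0],
                            sigmaP={"R": 0.5, "PL": 0.0, "J": 0.0, "SA": 0.0})
        rho, _ = draw_vital_rates(p, cov, seed=1)
        log_rho = np.log(rho)
        se = 0.5 / np.sqrt(T)
        assert abs(log_rho.mean() - 1.0) < 3 * se
        assert abs(log_rho.std() - 0.5) < 0.002

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="design width"):
            draw_vital_rates(
                VitalRateParams(zeta=[1.0, 1.0], beta=[0.0], eta=[0.0], gamma=[0.0],
                                sigmaP={"R": 0, "PL": 0, "J": 0, "SA": 0}),
                _intercept_design(4), seed=0,
            )

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sigmaP"):
            _params(sigma=-0.1)


class TestPropagateStates:
    def test_one_cohort_arithmetic(self):
        traj = propagate_states(100.0, np.array([2.0]), np.full((3, 1), 0.5))
        assert np.allclose(traj.n[:, 0], [200, 100, 50, 25])

    def test_identity_dynamics(self):
        eps = 1e-12
        traj = propagate_states(77.0, np.ones(5), np.full((3, 5), 1 - eps))
        assert np.allclose(traj.n, 77.0)

    def test_product_chain_recomputation(self, rng):
        T = 20
        rho = rng.uniform(0.5, 3.0, T)
        phi = rng.uniform(0.1, 0.9, (3, T))
        traj = propagate_states(1000.0, rho, phi)
        nA = 1000.0
        for t in range(T):
            nA *= rho[t] * phi[0, t] * phi[1, t] * phi[2, t]
            assert traj.n[3, t] == pytest.approx(nA, rel=1e-12)

    def test_trajectory_conservation(self, rng):
        T = 12
        rho = rng.uniform(0.5, 2.0, T)
        phi = rng.uniform(0.2, 0.8, (3, T))
        traj = propagate_states(500.0, rho, phi)
        total = 500.0 * np.prod(rho) * np.prod(phi)
        assert traj.n[3, -1] == pytest.approx(total, rel=1e-10)

    def test_non_positive_nA0_rejected(self):
        with pytest.raises(ValueError, match="nA0"):
            propagate_states(0.0, np.ones(2), np.full((3, 2), 0.5))


def _flat_trajectory(n_value, T):
    """A trajectory container with constant abundance, for observation MC tests."""
    return PopulationTrajectory(
        nA0=n_value, n=np.full((4, T), n_value),
        rho=np.ones(T), phi=np.full((3, T), 0.5),
    )


class TestObserve:
    def test_degenerate_noise_returns_truth(self):
        traj = _flat_trajectory(123.0, 4)
        obs = ObservationParams(cv={s: np.full(4, 1e-12) for s in STAGES})
        ds = observe(traj, obs, seed=0)
        assert np.allclose(ds.nhat, 123.0, rtol=1e-9)

    def test_mean_and_cv_monte_carlo(self):
        # psi_SA = 0.2, n = 1000, CV = 0.3: E[nhat] = 200, sample CV = 0.3
        T = 250_000
        traj = _flat_trajectory(1000.0, T)
        obs = ObservationParams(psi={"SA": 0.2}, cv={s: np.full(T, 0.3) for s in STAGES})
        ds = observe(traj, obs, seed=2)
        sa = ds.nhat[STAGES.index("SA")]
        se = 0.3 * 200 / np.sqrt(T)
        assert abs(sa.mean() - 200.0) < 3 * se
        assert sa.std() / sa.mean() == pytest.approx(0.3, abs=0.005)

    def test_sample_cv_invariant_to_psi(self):
        traj = _flat_trajectory(1000.0, 500)
        cv = {s: np.full(500, 0.4) for s in STAGES}
        a = observe(traj, ObservationParams(psi={"J": 0.5}, cv=cv), seed=7)
        b = observe(traj, ObservationParams(psi={"J": 1.0}, cv=cv), seed=7)
        j = STAGES.index("J")
        cv_a = a.nhat[j].std() / a.nhat[j].mean()
        cv_b = b.nhat[j].std() / b.nhat[j].mean()
        assert cv_a == pytest.approx(cv_b, rel=1e-12)

    def test_mean_preservation_across_psi_cv(self):
        # MC mean of nhat/(psi n) -> 1 within 3 MC SE for several (psi, CV)
        T = 200_000
        traj = _flat_trajectory(50.0, T)
        for i, (psi, cv) in enumerate([(0.5, 0.1), (1.0, 0.5), (0.2, 1.0)]):
            obs = ObservationParams(psi={"J": psi}, cv={s: np.full(T, cv) for s in STAGES})
            ds = observe(traj, obs, seed=10 + i)
            ratio = ds.nhat[STAGES.index("J")] / (psi * 50.0)
            se = cv / np.sqrt(T)
            assert abs(ratio.mean() - 1.0) < 3 * se

    def test_unresolved_noise_raises(self):
        traj = _flat_trajectory(10.0, 3)
        obs = ObservationParams(cv={"PL": np.full(3, 0.2)})  # other stages unset
        with pytest.raises(ValueError, match="unresolved"):
            observe(traj, obs, seed=0)


class TestMomentConversions:
    @pytest.mark.parametrize(
        "cv,expected",
        [(0.0, 0.0), (np.sqrt(np.e - 1), 1.0), (0.5, np.log(1.25))],
    )
    def test_cv_to_logvar_values(self, cv, expected):
        assert cv_to_logvar(cv) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("lv,expected", [(0.0, 0.0), (1.0, np.sqrt(np.e - 1))])
    def test_logvar_to_cv_values(self, lv, expected):
        assert logvar_to_cv(lv) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, x):
        assert logvar_to_cv(cv_to_logvar(x)) == pytest.approx(x, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cv_to_logvar(-0.1)
        with pytest.raises(ValueError):
            logvar_to_cv(-0.1)


class TestIndexMoments:
    def test_noise_free(self):
        assert index_moments(100.0, 1.0, 0.0) == (pytest.approx(100.0), pytest.approx(0.0))

    def test_biased_cell(self):
        mean, var = index_moments(1000.0, 0.2, np.log(1.09))
        assert mean == pytest.approx(200.0)
        assert var == pytest.approx(0.09 * 200**2, rel=1e-12)

    def test_matches_observe_sample_moments(self):
        T = 250_000
        traj = _flat_trajectory(400.0, T)
        cv = 0.6
        obs = ObservationParams(psi={"SA": 0.7}, cv={s: np.full(T, cv) for s in STAGES})
        ds = observe(traj, obs, seed=5)
        mean, var = index_moments(400.0, 0.7, cv_to_logvar(cv))
        sa = ds.nhat[STAGES.index("SA")]
        assert sa.mean() == pytest.approx(mean, rel=0.01)
        assert sa.var() == pytest.approx(var, rel=0.05)
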