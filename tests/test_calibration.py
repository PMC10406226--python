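"""Likelihood/prior kernels, per-patient fits, Gibbs blocks and the sampler."""

import math

import numpy as np
import pandas as pd
import pytest

from drinkdyn.calibration import (
    Chain,
    MixedEffectsSpec,
    MixedEffectsState,
    PatientData,
    PriorConfig,
    convergence_diagnostics,
    count_parameters,
    fit_mixed_effects,
    geweke_z,
    gibbs_beta,
    gibbs_psi,
    gibbs_sigma2,
    initial_frequentist_fit,
    log_likelihood,
    log_prior_effective,
    patient_data,
    per_patient_fit,
    summarize_posterior,
)
from drinkdyn.model import InitialConditions, ModelParameters, simulate
from drinkdyn.references import POPULATION_PARAMS, VARYING_PARAMS
from drinkdyn.synthetic import CohortSpec, generate_cohort


def make_patient(params, ics, horizon=84, sigma=0.0, seed=0, pid="T1"):
    """PatientData from an exact simulation plus optional noise (days >= 2)."""
    rng = np.random.default_rng(seed)
    t = simulate(params, ics, horizon)
    noise_a = rng.normal(0, sigma, horizon)
    noise_d = rng.normal(0, sigma, horizon)
    noise_a[0] = noise_d[0] = 0.0
    days = np.arange(1, horizon + 1)
    return PatientData(
        patient_id=pid,
        ics=ics,
        days_a=days,
        y_a=t.A + noise_a,
        days_d=days,
        y_d=t.D + noise_d,
        horizon=horizon,
    )


class TestCountParameters:
    @pytest.mark.parametrize("m, N, expected", [(9, 37, 388), (4, 37, 163), (1, 1, 4)])
    def test_totals(self, m, N, expected):
        assert count_parameters(m, N) == expected

    def test_components_for_full_model(self):
        m, N = 9, 37
        assert m * N == 333  # random effects
        assert m * (m + 1) // 2 == 45  # covariance elements
        assert m + m * N + 1 + m * (m + 1) // 2 == 388

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_parameters(0, 37)


class TestLikelihoodKernel:
    def setup_method(self):
        self.spec = MixedEffectsSpec()
        self.ics = InitialConditions(A0=8.4, A1=4.0, D1=7.0)
        self.theta = np.array(
            [getattr(POPULATION_PARAMS, p) for p in self.spec.varying]
        )

    def test_zero_residuals_give_zero(self):
        pdat = make_patient(POPULATION_PARAMS, self.ics)
        state = MixedEffectsState(
            beta=self.theta, effective=self.theta[None, :], sigma2=1.0, psi=np.eye(4)
        )
        assert log_likelihood([pdat], state, self.spec) == pytest.approx(0.0, abs=1e-18)

    def test_single_residual_closed_form(self):
        t = simulate(POPULATION_PARAMS, self.ics, 10)
        r, sigma2 = 1.7, 0.3
        pdat = PatientData(
            patient_id="x",
            ics=self.ics,
            days_a=np.array([5]),
            y_a=np.array([t.A[4] + r]),
            days_d=np.array([], dtype=int),
            y_d=np.array([]),
            horizon=10,
        )
        state = MixedEffectsState(
            beta=self.theta, effective=self.theta[None, :], sigma2=sigma2, psi=np.eye(4)
        )
        assert log_likelihood([pdat], state, self.spec) == pytest.approx(
            -(r**2) / (2 * sigma2)
        )

    def test_masking_a_day_removes_exactly_its_term(self):
        pdat = make_patient(POPULATION_PARAMS, self.ics, sigma=0.5, seed=3)
        state = MixedEffectsState(
            beta=self.theta, effective=self.theta[None, :], sigma2=1.0, psi=np.eye(4)
        )
        full = log_likelihood([pdat], state, self.spec)
        k = 10
        t = simulate(POPULATION_PARAMS, self.ics, pdat.horizon)
        term = -((pdat.y_a[k] - t.A[k]) ** 2) / 2.0
        masked = PatientData(
            patient_id="x",
            ics=pdat.ics,
            days_a=np.delete(pdat.days_a, k),
            y_a=np.delete(pdat.y_a, k),
            days_d=pdat.days_d,
            y_d=pdat.y_d,
            horizon=pdat.horizon,
        )
        assert log_likelihood([masked], state, self.spec) == pytest.approx(
            full - term, rel=1e-9
        )

    def test_additive_over_patients(self):
        p1 = make_patient(POPULATION_PARAMS, self.ics, sigma=0.5, seed=1, pid="a")
        p2 = make_patient(POPULATION_PARAMS, self.ics, sigma=0.5, seed=2, pid="b")
        state = MixedEffectsState(
            beta=self.theta,
            effective=np.vstack([self.theta, self.theta]),
            sigma2=0.7,
            psi=np.eye(4),
        )
        s1 = MixedEffectsState(
            beta=self.theta, effective=self.theta[None, :], sigma2=0.7, psi=np.eye(4)
        )
        assert log_likelihood([p1, p2], state, self.spec) == pytest.approx(
            log_likelihood([p1], s1, self.spec) + log_likelihood([p2], s1, self.spec)
        )


class TestPriorKernel:
    def test_no_deviation_gives_zero(self):
        beta = np.array([1.0, 2.0, 3.0, 4.0])
        state = MixedEffectsState(
            beta=beta, effective=np.tile(beta, (5, 1)), sigma2=1.0, psi=np.eye(4)
        )
        assert log_prior_effective(state) == pytest.approx(0.0)

    def test_unit_deviation_quadratic_form(self):
        beta = np.zeros(4)
        eff = np.zeros((1, 4))
        eff[0, 0] = 1.0
        state = MixedEffectsState(beta=beta, effective=eff, sigma2=1.0, psi=np.eye(4))
        assert log_prior_effective(state) == pytest.approx(-0.5)

    def test_translation_invariance(self, rng):
        beta = rng.standard_normal(4)
        eff = beta + rng.standard_normal((6, 4)) * 0.3
        psi = np.diag(rng.uniform(0.5, 2.0, 4))
        a = log_prior_effective(
            MixedEffectsState(beta=beta, effective=eff, sigma2=1.0, psi=psi)
        )
        shift = rng.standard_normal(4)
        b = log_prior_effective(
            MixedEffectsState(beta=beta + shift, effective=eff + shift, sigma2=1.0, psi=psi)
        )
        assert a == pytest.approx(b, rel=1e-12)


class TestPerPatientFit:
    def test_noiseless_recovery(self, noiseless_cohort):
        s = noiseless_cohort[0]
        est, resvar, diag = per_patient_fit(s)
        truth = s.truth.params
        for p in ("a1", "a2", "a3", "d1", "d2", "d3"):
            assert getattr(est, p) == pytest.approx(getattr(truth, p), abs=1e-3)
        assert resvar < 1e-10

    def test_objective_zero_at_generating_point(self, noiseless_cohort):
        s = noiseless_cohort[1]
        pdat = patient_data(s)
        assert pdat.ssr(s.truth.params) == pytest.approx(0.0, abs=1e-16)

    def test_residual_variance_tracks_noise_level(self):
        spec = CohortSpec(n_patients=1, sigma2=0.25, missingness=0.0, seed=77)
        s = generate_cohort(spec)[0]
        _, resvar, _ = per_patient_fit(s)
        assert resvar == pytest.approx(0.25, abs=0.1)


class TestFrequentistInitialization:
    def test_prior_seeds_from_small_cohort(self, noisy_cohort):
        priors, table = initial_frequentist_fit(noisy_cohort)
        assert priors.s0_squared == pytest.approx(0.25, abs=0.15)
        assert len(table) == len(noisy_cohort)
        # Psi0 is the IW scale centred on the estimate covariance: PD and
        # scaled by rho0 - dim - 1
        eigs = np.linalg.eigvalsh(priors.Psi0)
        assert np.all(eigs > 0)

    def test_identical_patients_jittered_to_pd(self, noiseless_cohort):
        one = noiseless_cohort[0]
        priors, _ = initial_frequentist_fit([one, one])
        assert np.all(np.linalg.eigvalsh(priors.Psi0) > 0)

    def test_median_start_near_population(self):
        spec = CohortSpec(n_patients=8, sigma2=0.25, missingness=0.0, seed=5)
        cohort = generate_cohort(spec)
        priors, _ = initial_frequentist_fit(cohort)
        beta_true = np.array([getattr(POPULATION_PARAMS, p) for p in VARYING_PARAMS])
        sds = np.array([0.0088, 0.4475, 0.2168, 0.3426])
        # medians land within ~2 population sds of the fixed effects
        assert np.all(np.abs(priors.beta0 - beta_true) < 2.5 * sds + 0.02)

    def test_single_patient_rejected(self, noisy_cohort):
        with pytest.raises(ValueError):
            initial_frequentist_fit(noisy_cohort[:1])


class TestGibbsBlocks:
    """Each conjugate draw matches its closed-form conditional's moments."""

    def test_beta_block_moments(self, rng):
        eff = rng.standard_normal((12, 3)) + np.array([1.0, -2.0, 0.5])
        psi = np.diag([0.4, 0.9, 0.2])
        draws = np.array([gibbs_beta(eff, psi, rng) for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), eff.mean(axis=0), atol=0.03)
        assert np.allclose(
            np.cov(draws, rowvar=False), psi / 12, atol=0.15 * psi.max() / 12 + 0.003
        )

    def test_sigma2_block_moments(self, rng):
        priors = PriorConfig(
            beta0=np.zeros(2), s0_squared=0.5, Psi0=np.eye(2), n0=1.0, rho0=100.0
        )
        ssr, n_obs = 80.0, 400
        shape = 0.5 * (priors.n0 + n_obs)
        rate = 0.5 * (priors.n0 * priors.s0_squared + ssr)
        draws = np.array([gibbs_sigma2(ssr, n_obs, priors, rng) for _ in range(4000)])
        mean_cf = rate / (shape - 1)
        var_cf = rate**2 / ((shape - 1) ** 2 * (shape - 2))
        assert draws.mean() == pytest.approx(mean_cf, rel=0.02)
        assert draws.var() == pytest.approx(var_cf, rel=0.2)

    def test_psi_block_moments(self, rng):
        m, N = 3, 15
        beta = np.zeros(m)
        eff = rng.standard_normal((N, m)) * 0.5
        priors = PriorConfig(
            beta0=beta, s0_squared=1.0, Psi0=2.0 * np.eye(m), n0=1.0, rho0=30.0
        )
        dev = eff - beta
        scale = priors.Psi0 + dev.T @ dev
        df = priors.rho0 + N
        mean_cf = scale / (df - m - 1)
        draws = np.array([gibbs_psi(eff, beta, priors, rng) for _ in range(3000)])
        assert np.allclose(draws.mean(axis=0), mean_cf, atol=0.06 * mean_cf.max())


class TestSamplerCorrectness:
    def test_linear_restriction_matches_conjugate_posterior(self):
        """With a1 = 0 the trajectory is affine in d3, so the exact posterior
        is Gaussian: effective ~ N(theta_hat, sigma2/Sxx) and the fixed
        effect is that convolved with the random-effect spread."""
        spec = MixedEffectsSpec(
            varying=("d3",),
            fixed_values={"a1": 0.0, "a2": 0.9, "a3": 0.1, "d1": 0.5, "d2": 0.6},
        )
        ics = InitialConditions(A0=2.0, A1=5.0, D1=3.0)
        theta_true, sigma, psi_val = 0.3, 0.5, 0.04
        gen = spec.build_params([theta_true])
        pdat = make_patient(gen, ics, horizon=40, sigma=sigma, seed=8)

        # closed form via two simulations: f(theta) = f0 + g * theta
        f0 = simulate(spec.build_params([0.0]), ics, 40)
        f1 = simulate(spec.build_params([1.0]), ics, 40)
        g = np.concatenate([f1.A - f0.A, f1.D - f0.D])
        y = np.concatenate([pdat.y_a, pdat.y_d])
        f0v = np.concatenate([f0.A, f0.D])
        sxx = float(g @ g)
        theta_hat = float(g @ (y - f0v)) / sxx
        var_theta = sigma**2 / sxx

        big = 1e8
        priors = PriorConfig(
            beta0=np.array([0.0]),
            s0_squared=sigma**2,
            n0=big,  # pins sigma2 at its true value
            Psi0=np.array([[psi_val * (big - 2)]]),
            rho0=big,  # pins psi
        )
        chain = fit_mixed_effects(
            [pdat],
            spec,
            priors,
            n_iter=8000,
            seed=3,
            start_effective=np.array([[0.0]]),
        )
        eff = chain.effective[:, 0, 0]
        beta = chain.beta[:, 0]
        sd_eff = math.sqrt(var_theta)
        assert eff.mean() == pytest.approx(theta_hat, abs=0.2 * sd_eff)
        assert eff.var() == pytest.approx(var_theta, rel=0.3)
        assert beta.mean() == pytest.approx(theta_hat, abs=0.2 * math.sqrt(var_theta + psi_val))
        assert beta.var() == pytest.approx(var_theta + psi_val, rel=0.3)

    def test_seed_reproducibility(self, noisy_cohort):
        data = [patient_data(s) for s in noisy_cohort]
        a = fit_mixed_effects(data, n_iter=300, seed=9)
        b = fit_mixed_effects(data, n_iter=300, seed=9)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.sigma2, b.sigma2)
        assert np.array_equal(a.psi, b.psi)
        assert np.array_equal(a.effective, b.effective)

    def test_reduced_sampler_modes_run(self, noisy_cohort):
        data = [patient_data(s) for s in noisy_cohort[:3]]
        plain_mh = fit_mixed_effects(
            data, n_iter=200, seed=1, adapt=False, delayed_rejection=False
        )
        am_only = fit_mixed_effects(
            data, n_iter=200, seed=1, adapt=True, delayed_rejection=False
        )
        assert plain_mh.n_kept == am_only.n_kept == 100
        assert np.all(plain_mh.acceptance <= 1.0)


def make_chain(beta_samples, sigma2=None, varying=("a2",)):
    K, m = beta_samples.shape
    sigma2 = np.ones(K) if sigma2 is None else sigma2
    return Chain(
        varying=varying,
        beta=beta_samples,
        effective=np.repeat(beta_samples[:, None, :], 3, axis=1),
        sigma2=sigma2,
        psi=np.repeat(np.eye(m)[None], K, axis=0),
        acceptance=np.full(3, 0.4),
        seed=0,
        n_iter=2 * K,
        burn=K,
    )


class TestSummariesAndDiagnostics:
    def test_degenerate_chain_summary(self):
        beta = np.tile(np.array([[0.5, -0.2, 0.3, 0.1]]), (50, 1))
        chain = make_chain(beta, varying=VARYING_PARAMS)
        table = summarize_posterior(chain).set_index("parameter")
        assert table.loc["a2", "population"] == pytest.approx(0.5)
        assert table.loc["a2", "sd"] == 0.0
        assert table.loc["a2", "mean"] == table.loc["a2", "median"]
        # fixed parameters echoed with zero spread
        assert table.loc["a1", "population"] == pytest.approx(0.2829)
        assert table.loc["a1", "sd"] == 0.0 and bool(table.loc["a1", "fixed"])

    def test_population_equals_mean_of_samples(self, rng):
        beta = rng.standard_normal((400, 4)) * 0.1 + 1.0
        chain = make_chain(beta, varying=VARYING_PARAMS)
        table = summarize_posterior(chain).set_index("parameter")
        assert table.loc["d2", "population"] == pytest.approx(beta[:, 2].mean())

    def test_white_noise_chain_diagnostics(self, rng):
        beta = rng.standard_normal((1000, 1))
        chain = make_chain(beta, sigma2=np.abs(rng.standard_normal(1000)) + 1.0)
        diag = convergence_diagnostics(chain).set_index("scalar")
        assert abs(diag.loc["beta_a2", "geweke_z"]) < 3.0
        assert diag.loc["beta_a2", "ess"] > 500

    def test_trending_chain_flagged(self):
        beta = np.linspace(0.0, 5.0, 1000)[:, None]
        chain = make_chain(beta)
        diag = convergence_diagnostics(chain).set_index("scalar")
        assert abs(diag.loc["beta_a2", "geweke_z"]) > 2.0
        assert bool(diag.loc["beta_a2", "flagged"])

    def test_constant_chain_ess_flagged(self):
        beta = np.ones((500, 1))
        chain = make_chain(beta, sigma2=np.ones(500))
        diag = convergence_diagnostics(chain).set_index("scalar")
        assert bool(diag.loc["beta_a2", "constant"])
        assert np.isnan(diag.loc["beta_a2", "ess"])

    def test_short_chain_rejected(self):
        chain = make_chain(np.ones((50, 1)))
        with pytest.raises(ValueError):
            convergence_diagnostics(chain)

    def test_geweke_zero_for_split_identical_halves(self):
        x = np.tile([1.0, -1.0], 500)
        assert abs(geweke_z(x)) < 1.0
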