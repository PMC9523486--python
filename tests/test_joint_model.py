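import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from tmbcat.data_model import Cohort
from tmbcat.joint_model import (
    FitOptions,
    JointModelFit,
    SeparationError,
    JointModelError,
    fit_joint_model,
    joint_probabilities,
    joint_probability,
)
from tmbcat.simulator import SimulationConfig, simulate_cohort


class TestFitDegenerateInputs:
    def test_all_responders_is_separation(self):
        cohort = Cohort.from_arrays(
            None, R=[1] * 25, T=np.linspace(1, 20, 25), delta=[1] * 25,
            tmb=np.linspace(1, 20, 25),
        )
        with pytest.raises(SeparationError):
            fit_joint_model(cohort)

    def test_tmb_perfectly_separating_detected(self):
        cohort = Cohort.from_arrays(
            None, R=[0] * 12 + [1] * 13, T=np.linspace(1, 20, 25),
            delta=[1] * 25, tmb=np.linspace(1, 25, 25),
        )
        with pytest.raises(SeparationError, match="separates"):
            fit_joint_model(cohort)

    def test_no_events_rejected(self):
        cohort = Cohort.from_arrays(
            None, R=[0, 1] * 13, T=np.linspace(1, 20, 26), delta=[0] * 26,
            tmb=np.linspace(1, 20, 26) % 7 + 1,
        )
        with pytest.raises(JointModelError, match="event"):
            fit_joint_model(cohort)

    def test_small_cohort_warns(self, tiny_cohort):
        with pytest.warns(UserWarning, match="unstable"):
            fit_joint_model(tiny_cohort, FitOptions(random_effects="none"))


class TestNoSignalLimit:
    def test_flat_truth_without_heterogeneity(self):
        """No TMB effect, no random effects: the fit reduces to the
        marginal response rate, a null hazard coefficient, and the
        variance floor."""
        cfg = SimulationConfig(n=500, beta0=-0.85, sigma_u=0.0, gamma=0.0)
        cohort, _ = simulate_cohort(cfg, seed=5)
        fit = fit_joint_model(cohort)
        pred = fit.beta[0] + fit.beta[1] * cohort.tmb.mean()
        assert pred == pytest.approx(logit(cohort.R.mean()), abs=0.15)
        assert abs(fit.alpha) < 0.05
        assert fit.sigma_u2 <= 1e-5  # ridge floor
        assert fit.gamma == 0.0


class TestOracleEquivalenceAtSigmaZero:
    def test_matches_separate_logistic_and_cox_fits(self):
        """With the random effects switched off the joint likelihood
        factorizes, so the estimates must equal standard GLM/Cox fits."""
        sm = pytest.importorskip("statsmodels.api")
        from lifelines import CoxPHFitter

        cfg = SimulationConfig(
            n=200, beta0=-0.5,
            effect_R={"kind": "linear", "slope": 0.3, "ref": 8.0},
            effect_T={"kind": "linear", "slope": -0.2, "ref": 8.0},
            sigma_u=0.0, gamma=0.0,
        )
        cohort, _ = simulate_cohort(cfg, seed=3)
        fit = fit_joint_model(cohort, FitOptions(random_effects="none"))
        X = sm.add_constant(cohort.tmb)
        glm = sm.GLM(cohort.R, X, family=sm.families.Binomial()).fit()
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": cohort.T, "E": cohort.delta, "x": cohort.tmb}), "T", "E"
        )
        assert np.abs(fit.beta - glm.params).max() < 1e-6
        assert abs(fit.alpha - cph.params_.iloc[0]) < 1e-6


class TestFitProperties:
    def test_loglik_trace_monotone_ascent(self, consistent_fit, null_fit):
        for fit in (consistent_fit, null_fit):
            tr = fit.loglik_trace
            assert np.all(np.diff(tr) >= -1e-5 * (1 + np.abs(tr[:-1])))

    def test_sigma_psd_and_rho_bounded(self, null_fit):
        eig = np.linalg.eigvalsh(null_fit.Sigma)
        assert eig.min() >= -1e-12
        assert abs(null_fit.rho) <= 1.0

    def test_baseline_hazard_nondecreasing_from_zero(self, consistent_fit):
        H0 = consistent_fit.H0
        assert H0(0.0) == 0.0
        assert np.all(np.diff(H0.values) >= 0)

    def test_serialization_round_trip(self, consistent_fit, tmp_path):
        path = tmp_path / "fit.json"
        consistent_fit.save(path)
        back = JointModelFit.load(path)
        np.testing.assert_allclose(back.beta, consistent_fit.beta)
        np.testing.assert_allclose(back.u_hat, consistent_fit.u_hat)
        p1 = joint_probabilities(consistent_fit, T0=6.0)["p"]
        p2 = joint_probabilities(back, T0=6.0)["p"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_parameter_recovery_single_seed(self):
        """Estimates at n=1000 fall within 3 replication SDs of the
        generative truth (SDs frozen from a 25-replicate pilot)."""
        cfg = SimulationConfig(
            n=1000, beta0=-1.0,
            effect_R={"kind": "linear", "slope": 0.5, "ref": 8.0},
            effect_T={"kind": "linear", "slope": -0.3, "ref": 8.0},
            sigma_u=0.5, gamma=1.0, tmb_sigma=0.4,
        )
        cohort, _ = simulate_cohort(cfg, seed=77)
        fit = fit_joint_model(cohort)
        assert fit.beta[1] == pytest.approx(0.5, abs=3 * 0.035)
        assert fit.alpha == pytest.approx(-0.3, abs=3 * 0.021)

    def test_bivariate_option_smoke(self, null_cohort):
        cohort, _ = null_cohort
        fit = fit_joint_model(cohort, FitOptions(random_effects="bivariate"))
        assert fit.Sigma.shape == (2, 2)
        assert np.linalg.eigvalsh(fit.Sigma).min() >= -1e-12
        assert abs(fit.rho) <= 1.0
        p = joint_probabilities(fit, T0=6.0)["p"]
        assert np.all((p >= 0) & (p <= 1))


class TestJointProbability:
    def test_t0_zero_gives_survival_one(self, consistent_fit, consistent_cohort):
        cohort, _ = consistent_cohort
        jp = joint_probability(consistent_fit, cohort.records[0], T0=0.0)
        assert jp.p_T == pytest.approx(1.0)
        assert jp.p == pytest.approx(jp.p_R)

    def test_sigma_zero_reduces_to_product(self):
        """Without random effects the integral equals the plain product
        expit(eta) * exp(-H0(T0) e^psi)."""
        cfg = SimulationConfig(n=120, beta0=-0.6, sigma_u=0.0, gamma=0.0)
        cohort, _ = simulate_cohort(cfg, seed=9)
        fit = fit_joint_model(cohort, FitOptions(random_effects="none"))
        rec = cohort.records[10]
        jp = joint_probability(fit, rec, T0=6.0, mode="integrate")
        eta, psi = fit.linear_predictors(rec.tmb)
        expected = float(expit(eta) * np.exp(-fit.H0(6.0) * np.exp(psi)))
        assert jp.p == pytest.approx(expected, abs=1e-12)

    def test_quadrature_agrees_with_monte_carlo(self, null_fit, null_cohort):
        """Gauss-Hermite integral vs a 10^6-draw Monte-Carlo oracle."""
        cohort, _ = null_cohort
        rec = cohort.records[3]
        jp = joint_probability(null_fit, rec, T0=6.0, mode="integrate")
        rng = np.random.default_rng(2024)
        u = rng.normal(0.0, np.sqrt(null_fit.sigma_u2), 1_000_000)
        v = null_fit.gamma * u
        draws = expit(null_fit.beta[0] + null_fit.beta[1] * rec.tmb + u) * np.exp(
            -null_fit.H0(6.0) * np.exp(null_fit.alpha * rec.tmb + v)
        )
        se = draws.std() / 1000.0
        assert jp.p == pytest.approx(draws.mean(), abs=3 * se)

    def test_monotone_nonincreasing_in_t0(self, null_fit, null_cohort):
        cohort, _ = null_cohort
        rec = cohort.records[0]
        grid = [0.0, 1.0, 3.0, 6.0, 12.0, 24.0]
        ps = [joint_probability(null_fit, rec, T0=t, mode="integrate").p for t in grid]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_t0_beyond_last_event_warns(self, consistent_fit, consistent_cohort):
        cohort, _ = consistent_cohort
        with pytest.warns(UserWarning, match="last"):
            joint_probability(consistent_fit, cohort.records[0], T0=1e6)

    def test_plugin_needs_fitted_patient(self, consistent_fit):
        from tmbcat.data_model import PatientRecord

        stranger = PatientRecord("nobody", 1, 5.0, 1, 9.0)
        with pytest.raises(JointModelError, match="not in the fitted cohort"):
            joint_probability(consistent_fit, stranger, T0=6.0, mode="plugin")


class TestJointProbabilitiesTable:
    def test_identical_patients_identical_p(self, null_fit):
        tab = joint_probabilities(null_fit, T0=6.0, mode="integrate")
        x = null_fit.tmb
        dup = np.isclose(x[:, None], x[None, :])
        i, j = np.nonzero(np.triu(dup, 1))
        if len(i):
            np.testing.assert_allclose(
                tab["p"].to_numpy()[i], tab["p"].to_numpy()[j], atol=1e-12
            )

    def test_weights_reduce_vector_dimension(self, null_fit):
        tab = joint_probabilities(null_fit, T0=6.0, weights=(1.0, 0.0))
        assert np.all(tab["p_T"] == 0.0)
        assert np.all(tab["p_R"] > 0.0)

    def test_permutation_equivariance(self, null_fit, null_cohort):
        cohort, _ = null_cohort
        perm = np.random.default_rng(0).permutation(cohort.n)
        shuffled = Cohort(tuple(cohort.records[i] for i in perm))
        t1 = joint_probabilities(null_fit, T0=6.0)
        t2 = joint_probabilities(null_fit, shuffled, T0=6.0)
        np.testing.assert_allclose(
            t1["p"].to_numpy()[perm], t2["p"].to_numpy(), atol=1e-12
        )

    def test_plugin_density_factor_can_exceed_one(self, null_fit):
        tab = joint_probabilities(null_fit, T0=0.0, mode="plugin")
        eb = joint_probabilities(null_fit, T0=0.0, mode="eb")
        assert not np.allclose(tab["p"], eb["p"])
        assert np.all((eb["p"] >= 0) & (eb["p"] <= 1))
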