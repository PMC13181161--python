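import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate as sp_integrate
from scipy import optimize, stats

from jointwiv.quadrature import integrate
from jointwiv.simulate import (
    SimulationConfig,
    apply_censoring,
    draw_subject_frame,
    generate_longitudinal,
    invert_event_time,
    linear_hazard_terms,
    simulate_dataset,
)


class TestEventTimeInversion:
    def test_u_equal_one_gives_zero(self):
        cfg = SimulationConfig(n_subjects=1)
        T = invert_event_time(np.array([1.0]), cfg, np.array([0.0]), 0.5, np.array([0.0]))
        assert T[0] == 0.0

    def test_numeric_root_oracle(self):
        # CumHaz(T) = (lam/B)(e^{BT} - 1) = -log u, solved independently
        cfg = SimulationConfig(n_subjects=1, lambda0=0.1)
        u, B = 0.5, 0.1
        T = invert_event_time(np.array([u]), cfg, np.array([0.0]), B, np.array([0.0]))[0]
        root = optimize.brentq(
            lambda t: (0.1 / B) * np.expm1(B * t) + np.log(u), 0.0, 100.0
        )
        assert T == pytest.approx(root, rel=1e-10)
        assert T == pytest.approx(5.2658903, abs=1e-6)

    def test_exponential_limit_at_zero_slope(self):
        cfg = SimulationConfig(n_subjects=1, lambda0=0.5)
        T = invert_event_time(
            np.array([np.exp(-1.0)]), cfg, np.array([0.0]), 0.0, np.array([0.0])
        )
        assert T[0] == pytest.approx(2.0, rel=1e-12)

    def test_negative_slope_can_preclude_event(self):
        cfg = SimulationConfig(n_subjects=1, lambda0=0.1)
        T = invert_event_time(
            np.array([1e-9]), cfg, np.array([0.0]), -1.0, np.array([0.0])
        )
        assert np.isinf(T[0])

    def test_invalid_uniform_draw(self):
        cfg = SimulationConfig(n_subjects=1)
        with pytest.raises(ValueError):
            invert_event_time(np.array([0.0]), cfg, np.array([0.0]), 0.1, np.array([0.0]))


class TestSubjectFrame:
    def test_zero_tau_gives_zero_random_effects(self, rng):
        cfg = SimulationConfig(n_subjects=50, tau=(0.0, 0.0, 0.0, 0.0))
        _, b = draw_subject_frame(cfg, rng)
        np.testing.assert_allclose(b, 0.0)

    def test_degenerate_binomial(self, rng):
        cfg = SimulationConfig(n_subjects=100, w1_prob=1.0)
        covs, _ = draw_subject_frame(cfg, rng)
        assert (covs["w1"] == 1.0).all()

    def test_random_effect_covariance_matches_tpt(self, rng):
        cfg = SimulationConfig(n_subjects=100_000)
        _, b = draw_subject_frame(cfg, rng)
        sigma = cfg.covariance().assemble()
        emp = np.cov(b.T)
        n = cfg.n_subjects
        for i in range(4):
            for j in range(4):
                se = np.sqrt((sigma[i, i] * sigma[j, j] + sigma[i, j] ** 2) / n)
                assert abs(emp[i, j] - sigma[i, j]) < 3 * se


class TestHazardTerms:
    def test_zero_alpha(self):
        cfg = SimulationConfig(n_subjects=1, alpha=(0.0, 0.0, 0.0, 0.0))
        A, B = linear_hazard_terms(cfg, np.zeros((1, 4)))
        assert A[0] == 0.0 and B == 0.0

    def test_single_biomarker_substitution(self):
        cfg = SimulationConfig(
            n_subjects=1,
            alpha=(1.0, 0.0, 0.0, 0.0),
            beta_mu=((2.190, -0.040), (1.040, 0.350)),
        )
        A, B = linear_hazard_terms(cfg, np.zeros((1, 4)))
        assert A[0] == pytest.approx(2.190)
        assert B == pytest.approx(-0.040)

    def test_composition_oracle(self, rng):
        """hazard via (A, B) equals hazard via the full LP association
        composed with the location-scale linear predictors."""
        cfg = SimulationConfig(n_subjects=5)
        _, b = draw_subject_frame(cfg, rng)
        A, B = linear_hazard_terms(cfg, b)
        t = rng.uniform(0, 10, 100)
        for i in range(5):
            eta_assoc = np.zeros_like(t)
            for k in range(2):
                mu_k = cfg.beta_mu[k][0] + b[i, k] + cfg.beta_mu[k][1] * t
                sig_k = cfg.beta_sigma[k][0] + b[i, 2 + k] + cfg.beta_sigma[k][1] * t
                eta_assoc += cfg.alpha[2 * k] * mu_k + cfg.alpha[2 * k + 1] * sig_k
            np.testing.assert_allclose(A[i] + B * t, eta_assoc, atol=1e-12)


class TestCensoring:
    def test_never_event(self, rng):
        cfg = SimulationConfig(n_subjects=3)
        obs, delta = apply_censoring(np.full(3, np.inf), cfg, rng)
        assert (delta == 0).all() and np.all(obs <= cfg.t_max)

    def test_immediate_event(self, rng):
        cfg = SimulationConfig(n_subjects=3)
        obs, delta = apply_censoring(np.zeros(3), cfg, rng)
        assert (delta == 1).all() and (obs == 0).all()

    def test_event_probability_against_integration_oracle(self, rng):
        # T ~ Exp(lam), T* ~ U(0, tmax): P(delta=1) = 1 - (1 - e^{-lam tmax})/(lam tmax)
        lam, tmax, n = 0.35, 8.0, 100_000
        cfg = SimulationConfig(n_subjects=n, t_max=tmax)
        T = rng.exponential(1.0 / lam, size=n)
        _, delta = apply_censoring(T, cfg, rng)
        oracle, _ = sp_integrate.quad(
            lambda s: (1.0 - np.exp(-lam * s)) / tmax, 0.0, tmax
        )
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert abs(delta.mean() - oracle) < 3 * se


class TestLongitudinal:
    def test_short_follow_up_keeps_baseline_visit(self, rng):
        cfg = SimulationConfig(n_subjects=1)
        rows = generate_longitudinal(0, 0.5, cfg, np.zeros(4), rng)
        assert sorted(rows["time"].unique()) == [0.0]
        assert len(rows) == 2  # one row per biomarker

    def test_zero_noise_reproduces_linear_predictor(self, rng):
        cfg = SimulationConfig(
            n_subjects=1, beta_sigma=((-40.0, 0.0), (-40.0, 0.0))
        )
        rows = generate_longitudinal(0, 5.0, cfg, np.zeros(4), rng)
        y1 = rows[rows.biomarker == 1].sort_values("time")
        expected = cfg.beta_mu[0][0] + cfg.beta_mu[0][1] * y1["time"].to_numpy()
        np.testing.assert_allclose(y1["value"].to_numpy(), expected, atol=1e-12)

    def test_marginal_noise_scale(self, rng):
        # flat submodels: every visit shares one Gaussian law, so the pooled
        # sample SD estimates exp(beta0_sigma1)
        cfg = SimulationConfig(
            n_subjects=1,
            beta_mu=((2.19, 0.0), (1.04, 0.0)),
            beta_sigma=((-1.36, 0.0), (0.16, 0.0)),
            visit_spacing=0.0005,
        )
        rows = generate_longitudinal(0, 5.0, cfg, np.zeros(4), rng)
        y1 = rows[rows.biomarker == 1]["value"].to_numpy()
        sd = y1.std(ddof=1)
        n = y1.size
        assert n > 9000
        se = np.exp(-1.36) / np.sqrt(2 * n)
        assert abs(sd - np.exp(-1.36)) < 4 * se


class TestSimulateDataset:
    def test_empty_configuration(self):
        long_data, surv_data, truth = simulate_dataset(SimulationConfig(n_subjects=0))
        assert long_data is None and surv_data is None
        assert truth["beta_mu1_intercept"] == 2.190

    def test_default_truth_matches_study_inputs(self):
        truth = SimulationConfig().truth()
        assert truth["beta_sigma1_intercept"] == -1.360
        assert truth["gamma_w2"] == -2.300
        assert truth["alpha_sigma1"] == 1.900
        assert truth["tau_sigma2"] == 0.160
        assert SimulationConfig().n_subjects == 1000

    def test_kaplan_meier_against_exponential_survival(self):
        """With gamma = alpha = 0 event times are Exp(lambda); the analytic
        survival curve must lie inside the Kaplan-Meier 95% band."""
        lifelines = pytest.importorskip("lifelines")
        lam = 0.25
        cfg = SimulationConfig(
            n_subjects=3000,
            lambda0=lam,
            gamma=(0.0, 0.0),
            alpha=(0.0, 0.0, 0.0, 0.0),
            seed=5,
        )
        _, surv_data, _ = simulate_dataset(cfg)
        km = lifelines.KaplanMeierFitter().fit(
            surv_data.table["time"], surv_data.table["event"]
        )
        grid = np.linspace(0.3, 6.0, 12)
        band = km.confidence_interval_survival_function_
        lo = np.interp(grid, band.index, band.iloc[:, 0])
        hi = np.interp(grid, band.index, band.iloc[:, 1])
        target = np.exp(-lam * grid)
        assert np.all((target >= lo) & (target <= hi))

    def test_inverse_cdf_identity_via_quadrature(self):
        """Cross-module oracle: the Gauss-Kronrod cumulative hazard of the
        generating hazard, evaluated at the drawn event time, returns the
        inversion's -log U."""
        cfg = SimulationConfig(n_subjects=200, seed=9)
        _, surv, truth = simulate_dataset(cfg)
        meta = truth["_meta"]
        surv_ids = np.isfinite(meta["event_times"])
        w = surv.table[["w1", "w2"]].to_numpy()
        wg = w @ np.array(cfg.gamma)
        worst = 0.0
        for i in np.flatnonzero(surv_ids):
            T = meta["event_times"][i]
            rate0 = cfg.lambda0 * np.exp(wg[i] + meta["A"][i])
            B = meta["B"]
            cum = integrate(lambda s: rate0 * np.exp(B * s), 0.0, T)
            worst = max(worst, abs(cum + np.log(meta["uniform_draws"][i])))
        assert worst < 1e-8

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_structural_invariants(self, seed):
        cfg = SimulationConfig(n_subjects=30, seed=seed)
        long_data, surv_data, _ = simulate_dataset(cfg)
        tab = surv_data.table
        assert (tab["time"] <= cfg.t_max).all()
        assert set(tab["event"].unique()) <= {0, 1}
        last = long_data.last_visit_times()
        obs = tab.set_index("id")["time"]
        assert (last <= obs.reindex(last.index) + 1e-12).all()

    def test_event_times_pass_exponential_gof(self):
        """B = 0 configuration: event times within one covariate stratum are
        exactly exponential; Kolmogorov-Smirnov should not reject."""
        cfg = SimulationConfig(
            n_subjects=4000,
            lambda0=0.4,
            gamma=(0.7, 0.0),
            alpha=(0.0, 0.0, 0.0, 0.0),
            seed=13,
        )
        _, _, truth = simulate_dataset(cfg)
        meta = truth["_meta"]
        _, surv, _ = simulate_dataset(cfg)
        w1 = surv.table["w1"].to_numpy()
        for val in (0.0, 1.0):
            times = meta["event_times"][w1 == val]
            rate = cfg.lambda0 * np.exp(cfg.gamma[0] * val)
            p = stats.kstest(times, "expon", args=(0.0, 1.0 / rate)).pvalue
            assert p > 0.01
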