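import numpy as np
import pytest
from scipy import stats

from jointwiv.data import SurvivalRecord
from jointwiv.likelihood import (
    AssociationSpec,
    association_predictor,
    cumulative_hazard,
    event_loglik,
    hazard_at,
    linear_predictor,
    longitudinal_loglik,
    residual_sd,
)
from jointwiv.design import DesignBlock
from jointwiv.quadrature import default_rule
from jointwiv.splines import BaselineHazardSpline


def _block(times, subject_index, n_random=1):
    times = np.asarray(times, dtype=float)
    X = np.column_stack([np.ones_like(times), times])
    Z = np.ones((times.size, n_random))
    return DesignBlock(
        fixed_matrix=X,
        random_matrix=Z,
        submodel_tag="mu",
        biomarker_tag=1,
        fixed_terms=("1", "time"),
        random_terms=("1",),
        subject_index=np.asarray(subject_index),
    )


def _record(entry=0.0, time=5.0, event=1, w=(0.0,)):
    return SurvivalRecord(
        subject_id=0,
        entry_time=entry,
        observed_time=time,
        event=event,
        covariates=np.asarray(w, dtype=float),
    )


class TestLinearPredictor:
    def test_zero_parameters_give_zero(self):
        block = _block([0.0, 1.0, 2.0], [0, 0, 0])
        eta = linear_predictor(block, np.zeros(2), np.zeros((1, 1)))
        np.testing.assert_allclose(eta, 0.0)

    def test_intercept_plus_random_intercept(self):
        block = _block([0.0], [0])
        eta = linear_predictor(block, np.array([2.190, 0.0]), np.array([[0.5]]))
        assert eta[0] == pytest.approx(2.690)

    def test_time_slope(self):
        block = _block([10.0], [0])
        eta = linear_predictor(block, np.array([2.190, -0.040]), np.zeros((1, 1)))
        assert eta[0] == pytest.approx(1.790)

    def test_linearity_in_beta(self, rng):
        block = _block(rng.uniform(0, 5, 7), [0, 1, 0, 1, 0, 1, 0])
        b = rng.standard_normal((2, 1))
        b1, b2 = rng.standard_normal(2), rng.standard_normal(2)
        lhs = linear_predictor(block, b1 + b2, b)
        rhs = linear_predictor(block, b1, b) + linear_predictor(block, b2, np.zeros((2, 1)))
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_dimension_mismatch(self):
        block = _block([0.0], [0])
        with pytest.raises(ValueError):
            linear_predictor(block, np.zeros(3), np.zeros((1, 1)))


class TestResidualSD:
    def test_values(self):
        np.testing.assert_allclose(residual_sd(np.array([0.0])), 1.0)
        assert residual_sd(np.array([np.log(2.0)]))[0] == pytest.approx(2.0)
        assert residual_sd(np.array([-1.360]))[0] == pytest.approx(np.exp(-1.360))

    def test_overflow_guard(self):
        assert np.isfinite(residual_sd(np.array([1e4]))[0])


class TestLongitudinalLoglik:
    def test_at_the_mean_unit_sd(self):
        val = longitudinal_loglik(np.array([1.0]), np.array([1.0]), np.array([0.0]))
        assert val[0] == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_one_sigma_residual_any_scale(self, rng):
        eta_sigma = rng.standard_normal(5)
        y = np.exp(eta_sigma)  # y - eta_mu = sigma with eta_mu = 0
        val = longitudinal_loglik(y, np.zeros(5), eta_sigma)
        np.testing.assert_allclose(val, -0.5 * np.log(2 * np.pi) - eta_sigma - 0.5)

    def test_numeric_example(self):
        val = longitudinal_loglik(np.array([1.0]), np.array([0.0]), np.array([np.log(2.0)]))
        assert val[0] == pytest.approx(-0.5 * np.log(2 * np.pi) - np.log(2.0) - 0.125)

    def test_reduces_to_constant_variance_gaussian(self, rng):
        y = rng.standard_normal(20)
        mu = rng.standard_normal(20)
        s = 0.7
        ours = longitudinal_loglik(y, mu, np.full(20, np.log(s)))
        oracle = stats.norm(mu, s).logpdf(y)
        np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            longitudinal_loglik(np.zeros(2), np.zeros(3), np.zeros(3))


class TestAssociation:
    def test_zero_alpha(self):
        for structure in ("CV", "LP"):
            spec = AssociationSpec(structure, np.zeros(4))
            assert association_predictor(spec, np.zeros(2), np.zeros(2)) == 0.0
        assert association_predictor(AssociationSpec("RE", np.zeros(4)), b=np.ones(4)) == 0.0

    def test_lp_single_biomarker_example(self):
        spec = AssociationSpec("LP", np.array([-2.240, 1.900]))
        val = association_predictor(spec, np.array([2.0]), np.array([-1.36]))
        assert val == pytest.approx(-2.240 * 2.0 + 1.900 * (-1.36))

    def test_cv_sd_scale(self):
        spec = AssociationSpec("CV", np.array([0.0, 0.7]))
        # eta_sigma = 0 -> exp(0) = 1 -> contribution exactly alpha_sigma
        assert association_predictor(spec, np.array([5.0]), np.array([0.0])) == pytest.approx(0.7)

    def test_re_structure(self, rng):
        alpha = rng.standard_normal(4)
        b = rng.standard_normal(4)
        val = association_predictor(AssociationSpec("RE", alpha), b=b)
        assert val == pytest.approx(float(alpha @ b))

    def test_missing_inputs_raise(self):
        with pytest.raises(ValueError):
            association_predictor(AssociationSpec("RE", np.ones(2)))
        with pytest.raises(ValueError):
            association_predictor(AssociationSpec("LP", np.ones(2)))
        with pytest.raises(ValueError):
            AssociationSpec("XX", np.ones(2))


class TestHazard:
    def _flat_spline(self, log_lambda, hi=10.0):
        return BaselineHazardSpline.with_equal_knots(
            (0.0, hi), coefficients=np.full(6, log_lambda)
        )

    def test_constant_baseline(self):
        spline = self._flat_spline(np.log(0.3))
        h = hazard_at(np.linspace(0, 10, 9), _record(), spline, np.zeros(1))
        np.testing.assert_allclose(h, 0.3, rtol=1e-12)

    def test_proportional_hazards_in_covariates(self):
        spline = self._flat_spline(-1.0)
        spline.coefficients = np.array([0.1, -0.4, 0.8, 0.2, -0.1, 0.5])
        t = np.linspace(0.5, 9.5, 7)
        r1 = _record(w=(1.0,))
        r2 = _record(w=(0.0,))
        gamma = np.array([np.log(2.0)])
        ratio = hazard_at(t, r1, spline, gamma) / hazard_at(t, r2, spline, gamma)
        np.testing.assert_allclose(ratio, 2.0, rtol=1e-12)

    def test_loglinear_hazard_from_association(self):
        # log h = A' + B t via a constant baseline plus a linear association
        A, B = -0.7, 0.13
        spline = self._flat_spline(0.0)
        h = hazard_at(
            np.array([0.0, 2.0, 7.0]),
            _record(),
            spline,
            np.zeros(1),
            assoc=lambda t: A + B * t,
        )
        np.testing.assert_allclose(h, np.exp(A + B * np.array([0.0, 2.0, 7.0])), rtol=1e-12)

    def test_cumulative_hazard_constant(self):
        val = cumulative_hazard(_record(time=4.0), lambda s: np.full_like(s, 0.25))
        assert val == pytest.approx(1.0, rel=1e-14)

    def test_cumulative_hazard_closed_form_loglinear(self):
        A, B, T = -1.2, 0.31, 8.0
        val = cumulative_hazard(_record(time=T), lambda s: np.exp(A + B * s))
        assert val == pytest.approx(np.exp(A) * np.expm1(B * T) / B, rel=1e-10)

    def test_cumulative_hazard_left_truncation_additivity(self):
        fn = lambda s: np.exp(-0.5 + 0.2 * s + 0.1 * np.cos(s))
        whole = cumulative_hazard(_record(entry=0.0, time=5.0), fn)
        head = cumulative_hazard(_record(entry=0.0, time=2.0), fn)
        tail = cumulative_hazard(_record(entry=2.0, time=5.0), fn)
        assert tail == pytest.approx(whole - head, abs=1e-10)
        assert cumulative_hazard(_record(entry=3.0, time=3.0), fn) == 0.0

    def test_event_loglik_exponential_cases(self):
        lam = 0.4
        const = lambda s: np.full_like(s, lam)
        censored = event_loglik(_record(entry=1.0, time=5.0, event=0), const)
        assert censored == pytest.approx(-lam * 4.0, rel=1e-12)
        observed = event_loglik(_record(time=5.0, event=1), const)
        assert observed == pytest.approx(np.log(lam) - lam * 5.0, rel=1e-12)

    def test_event_loglik_spline_hazard_vs_trapezoid_oracle(self):
        # gently varying coefficients, as a penalized fit would produce
        spline = BaselineHazardSpline.with_equal_knots(
            (0.0, 10.0), coefficients=np.array([-1.5, -1.4, -1.3, -1.2, -1.1, -1.0])
        )
        rec = _record(entry=0.5, time=7.0, event=1)
        hz = lambda s: np.exp(spline.log_baseline(s))
        val = event_loglik(rec, hz, default_rule())
        grid = np.linspace(rec.entry_time, rec.observed_time, 100_001)
        oracle = np.log(hz(np.array([7.0]))[0]) - np.trapezoid(hz(grid), grid)
        assert val == pytest.approx(oracle, abs=1e-6)
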