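import numpy as np
import pytest
from scipy import stats

from jointwiv.data import survival_records
from jointwiv.likelihood import (
    association_predictor,
    event_loglik,
    longitudinal_loglik,
)
from jointwiv.likelihood import AssociationSpec
from jointwiv.posterior import ModelContext, ModelSpec
from jointwiv.priors import PriorConfig, normal_logpdf_sum


@pytest.fixture(scope="module", params=["LP", "CV", "RE", "constant_variance"])
def context(request, tiny_joint_data):
    long_data, surv_data, _ = tiny_joint_data
    if request.param == "constant_variance":
        spec = ModelSpec.constant_variance(2)
    else:
        spec = ModelSpec(association=request.param)
    return ModelContext(long_data, surv_data, spec)


def test_gradient_matches_finite_differences(context, rng):
    u = 0.3 * rng.standard_normal(context.dim)
    lp, g = context.logp_and_grad(u)
    assert np.isfinite(lp)
    idx = list(range(context.n_fixed)) + list(
        rng.integers(context.n_fixed, context.dim, 8)
    )
    h = 1e-6
    for i in idx:
        up, um = u.copy(), u.copy()
        up[i] += h
        um[i] -= h
        fd = (context.logp_and_grad(up)[0] - context.logp_and_grad(um)[0]) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=5e-5, abs=1e-6)


def test_pointwise_loglik_sums_to_total(context, rng):
    u = 0.2 * rng.standard_normal(context.dim)
    nat = context.unpack(u)
    total, _, per_subject = context._loglik_and_grads(nat, want_grad=False)
    assert per_subject.shape == (context.N,)
    assert per_subject.sum() == pytest.approx(total, rel=1e-12)
    np.testing.assert_allclose(context.pointwise_loglik(u), per_subject)


def test_fused_likelihood_matches_closure_reference(tiny_joint_data, rng):
    """Dual-route check: the vectorised likelihood used in sampling must
    agree with the closure-style per-subject reference functions."""
    long_data, surv_data, _ = tiny_joint_data
    for assoc in ("LP", "CV", "RE"):
        context = ModelContext(long_data, surv_data, ModelSpec(association=assoc))
        u = 0.25 * rng.standard_normal(context.dim)
        nat = context.unpack(u)
        total, _, _ = context._loglik_and_grads(nat, want_grad=False)

        # longitudinal part via the reference function
        ref = 0.0
        for k in (1, 2):
            o = context.obs[k]
            eta_mu = o["X_mu"] @ nat["beta_mu"][k - 1] + nat["b"][
                o["subj"], context.re_slices[("mu", k)]
            ].reshape(-1)
            eta_sig = o["X_sig"] @ nat["beta_sigma"][k - 1] + nat["b"][
                o["subj"], context.re_slices[("sigma", k)]
            ].reshape(-1)
            ref += longitudinal_loglik(o["y"], eta_mu, eta_sig).sum()
        # event part via closures
        if assoc == "RE":
            aspec = AssociationSpec("RE", nat["alpha"])
        else:
            aspec = AssociationSpec(assoc, nat["alpha"])
        spline = context.spline
        spline.coefficients = nat["gamma_h0"]
        for i, rec in enumerate(survival_records(surv_data)):
            def assoc_fn(times, i=i):
                out = np.empty(np.atleast_1d(times).size)
                eta_mu, eta_sig = context.linear_predictors_at(
                    nat, i, np.atleast_1d(times)
                )
                for j in range(out.size):
                    out[j] = association_predictor(
                        aspec, eta_mu[:, j], eta_sig[:, j], b=nat["b"][i]
                    )
                return out

            wgam = float(context.W[i] @ nat["gamma"])
            hz = lambda s, i=i, wgam=wgam: np.exp(
                spline.log_baseline(s) + wgam + assoc_fn(s, i)
            )
            ref += event_loglik(rec, hz, context.rule)
        assert total == pytest.approx(ref, rel=1e-9)


def test_fused_kernels_match_reference_path(tiny_joint_data, rng):
    """The numba fast path and the numpy reference path must agree on the
    log-likelihood, the per-subject contributions and every gradient."""
    from jointwiv._kernels import HAVE_NUMBA

    if not HAVE_NUMBA:
        pytest.skip("numba unavailable; only the reference path exists")
    long_data, surv_data, _ = tiny_joint_data
    for assoc in ("LP", "CV"):
        context = ModelContext(long_data, surv_data, ModelSpec(association=assoc))
        assert context._fast
        u = 0.25 * rng.standard_normal(context.dim)
        nat = context.unpack(u)
        ll_f, g_f, ps_f = context._loglik_and_grads_fast(nat)
        context._fast = False
        ll_s, g_s, ps_s = context._loglik_and_grads(nat)
        context._fast = True
        assert ll_f == pytest.approx(ll_s, rel=1e-10)
        np.testing.assert_allclose(ps_f, ps_s, rtol=1e-9)
        np.testing.assert_allclose(g_f["G_b"], g_s["G_b"], rtol=1e-8, atol=1e-12)
        for key in ("gamma", "alpha", "gamma_h0"):
            np.testing.assert_allclose(g_f[key], g_s[key], rtol=1e-8, atol=1e-12)
        for k in range(2):
            np.testing.assert_allclose(g_f["beta_mu"][k], g_s["beta_mu"][k], rtol=1e-8)
            np.testing.assert_allclose(
                g_f["beta_sigma"][k], g_s["beta_sigma"][k], rtol=1e-8
            )


def test_parameterisation_identity(tiny_joint_data, rng):
    """The unconstrained-space posterior equals the natural-space posterior
    plus the change-of-variables terms: both parameterisations define the
    same distribution."""
    long_data, surv_data, _ = tiny_joint_data
    context = ModelContext(long_data, surv_data, ModelSpec())
    for _ in range(3):
        u = 0.3 * rng.standard_normal(context.dim)
        nat = context.unpack(u)
        lp_u, _ = context.logp_and_grad(u)
        lp_nat = context.log_posterior_natural(
            beta_mu=nat["beta_mu"],
            beta_sigma=nat["beta_sigma"],
            tau=nat["tau"],
            corr=nat["P"],
            gamma=nat["gamma"],
            alpha=nat["alpha"],
            gamma_h0=nat["gamma_h0"],
            tau_h=nat["tau_h"],
            b=nat["b"],
        )
        # change of variables: log-tau, logit tau_h, correlation transform,
        # and the z -> b reparameterisation determinant per subject
        from jointwiv.covariance import corr_transform_logdet_and_lkj

        jac = float(np.sum(np.log(nat["tau"])))
        p01 = nat["tau_h"] / context.spec.priors.tau_h_scale
        jac += np.log(p01) + np.log1p(-p01)
        corr_lp, L_P = corr_transform_logdet_and_lkj(
            nat["corr_raw"], context.D, context.spec.priors.lkj_eta
        )
        # corr_lp includes the LKJ density on L; natural side carries the
        # LKJ density on P (equal for eta = 1 up to the same constant zero)
        jac += corr_lp
        # the z-innovation prior drops its Gaussian constant, while the
        # natural-space MVN(b; TPT) carries both the constant and log|Sigma|;
        # b = M z with |det M| = prod(tau) * prod(diag L_P)
        log_det_M = float(
            np.sum(np.log(nat["tau"])) + np.sum(np.log(np.diag(L_P)))
        )
        expected = (
            lp_nat
            + jac
            + context.N * log_det_M
            + context.N * context.D * 0.5 * np.log(2 * np.pi)
        )
        assert lp_u == pytest.approx(expected, rel=1e-8)


def test_association_zero_factorises(tiny_joint_data, rng):
    """With alpha = 0 the joint log posterior separates: changing gamma_h0
    leaves the longitudinal part untouched and vice versa."""
    long_data, surv_data, _ = tiny_joint_data
    context = ModelContext(long_data, surv_data, ModelSpec())
    u = 0.2 * rng.standard_normal(context.dim)
    u[context.slices["alpha"]] = 0.0
    nat = context.unpack(u)
    _, _, per_subject = context._loglik_and_grads(nat, want_grad=False)
    # perturb the longitudinal block only; event contribution must not move
    u2 = u.copy()
    u2[context.slices["beta_sigma1"]] += 0.37
    nat2 = context.unpack(u2)
    _, _, per_subject2 = context._loglik_and_grads(nat2, want_grad=False)
    # isolate event parts by zeroing out the longitudinal likelihood:
    # difference of totals equals difference of longitudinal parts alone
    delta = per_subject2 - per_subject
    o = context.obs[1]
    eta_mu = o["X_mu"] @ nat["beta_mu"][0] + nat["b"][o["subj"], 0]
    for nat_i, sign in ((nat, -1.0), (nat2, +1.0)):
        pass
    long1 = longitudinal_loglik(
        o["y"],
        eta_mu,
        o["X_sig"] @ nat["beta_sigma"][0] + nat["b"][o["subj"], 2],
    )
    long2 = longitudinal_loglik(
        o["y"],
        eta_mu,
        o["X_sig"] @ nat2["beta_sigma"][0] + nat2["b"][o["subj"], 2],
    )
    expected = np.bincount(o["subj"], weights=long2 - long1, minlength=context.N)
    np.testing.assert_allclose(delta, expected, atol=1e-10)


def test_intercept_interweave_is_likelihood_invariant(tiny_joint_data, rng):
    """The interweaving Gibbs move shifts fixed intercepts against the
    random-intercept means; every linear predictor, hence the likelihood,
    must be exactly unchanged."""
    long_data, surv_data, _ = tiny_joint_data
    context = ModelContext(long_data, surv_data, ModelSpec())
    u = 0.3 * rng.standard_normal(context.dim)
    ll0, _, ps0 = context._loglik_and_grads(context.unpack(u), want_grad=False)
    moved = False
    for _ in range(5):
        u2 = context.intercept_interweave(u, rng)
        ll2, _, ps2 = context._loglik_and_grads(context.unpack(u2), want_grad=False)
        assert ll2 == pytest.approx(ll0, abs=1e-8)
        np.testing.assert_allclose(ps2, ps0, atol=1e-8)
        moved |= bool(np.any(u2 != u))
        u = u2
    assert moved  # the move actually explores


def test_out_of_support_parameters(tiny_joint_data):
    long_data, surv_data, _ = tiny_joint_data
    context = ModelContext(long_data, surv_data, ModelSpec())
    K, D = context.K, context.D
    args = dict(
        beta_mu=[np.zeros(2)] * K,
        beta_sigma=[np.zeros(2)] * K,
        corr=np.eye(D),
        gamma=np.zeros(2),
        alpha=np.zeros(context.n_alpha),
        gamma_h0=np.full(6, -2.0),
        tau_h=0.5,
        b=np.zeros((context.N, D)),
    )
    assert context.log_posterior_natural(tau=np.array([0.0, 1, 1, 1]), **args) == -np.inf
    assert np.isfinite(context.log_posterior_natural(tau=np.ones(D), **args))
    bad = dict(args, tau_h=1.5)
    assert context.log_posterior_natural(tau=np.ones(D), **bad) == -np.inf
    with pytest.raises(ValueError):
        context.pack_natural(tau=np.zeros(D), **args)


def test_single_subject_term_sum_oracle(rng):
    """One subject, one visit per biomarker: the natural-space log posterior
    equals the sum of independently computed terms."""
    import pandas as pd

    from jointwiv.data import LongitudinalDataset, SurvivalData

    long_df = pd.DataFrame(
        {
            "id": [0, 0],
            "time": [0.0, 0.0],
            "biomarker": [1, 2],
            "value": [1.7, 0.4],
        }
    )
    surv_df = pd.DataFrame(
        {"id": [0], "entry": [0.0], "time": [2.0], "event": [1], "w1": [1.0]}
    )
    ld, sd = LongitudinalDataset(long_df), SurvivalData(surv_df)
    context = ModelContext(ld, sd, ModelSpec(center=False))
    D = context.D
    beta_mu = [np.array([0.9, -0.1]), np.array([0.2, 0.05])]
    beta_sigma = [np.array([-0.5, 0.0]), np.array([0.1, 0.0])]
    tau = np.array([0.8, 0.5, 0.4, 0.2])
    corr = np.eye(4)
    gamma = np.array([0.3])
    alpha = np.zeros(4)
    log_lam = -1.1
    gamma_h0 = np.full(6, log_lam)
    b = np.array([[0.25, -0.3, 0.1, 0.05]])
    tau_h = 0.5

    value = context.log_posterior_natural(
        beta_mu, beta_sigma, tau, corr, gamma, alpha, gamma_h0, tau_h, b
    )

    # independent term-by-term reconstruction
    expected = 0.0
    for k, y in ((1, 1.7), (2, 0.4)):
        eta_mu = beta_mu[k - 1][0] + b[0, k - 1]
        eta_sig = beta_sigma[k - 1][0] + b[0, 2 + k - 1]
        expected += float(
            longitudinal_loglik(np.array([y]), np.array([eta_mu]), np.array([eta_sig]))[0]
        )
    lam_i = np.exp(log_lam + 0.3)  # constant hazard x covariate effect
    expected += np.log(lam_i) - lam_i * 2.0  # exponential event loglik
    expected += float(stats.multivariate_normal(np.zeros(4), np.diag(tau**2)).logpdf(b[0]))
    pri = PriorConfig()
    for v in beta_mu + beta_sigma:
        expected += normal_logpdf_sum(np.asarray(v, float), pri.beta_prior)[0]
    expected += normal_logpdf_sum(gamma, pri.gamma_prior)[0]
    expected += normal_logpdf_sum(alpha, pri.alpha_prior)[0]
    q = tau**2 / (pri.tau_prior.df * pri.tau_prior.scale**2)
    expected += float(np.sum(-0.5 * (pri.tau_prior.df + 1) * np.log1p(q)))
    expected += 0.5 * context.spline.pen_rank * np.log(tau_h)  # flat spline: no penalty
    assert value == pytest.approx(expected, rel=1e-10)
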