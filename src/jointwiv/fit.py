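"""Model fitting, diagnostics and posterior prediction.

``fit`` draws from the joint posterior with the in-package NUTS sampler
(non-centered random effects); ``fit_constant_variance`` is the standard
joint-model comparator in which each biomarker's residual SD is a single
constant with no random effect and no WIV association term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .data import LongitudinalDataset, SurvivalData
from .posterior import ModelContext, ModelSpec
from .priors import PriorConfig
from .sampler import SamplerStats, nuts_sample

RHAT_THRESHOLD = 1.05


@dataclass
class FitResult:
    """Posterior draws plus diagnostics for one model fit."""

    context: ModelContext
    draws_unconstrained: np.ndarray  # (chains, draws, dim)
    posterior: dict[str, np.ndarray]  # name -> (chains, draws) natural scale
    b_draws: np.ndarray  # (chains, draws, N, D)
    pointwise_loglik: np.ndarray  # (chains, draws, N)
    sampler_stats: list[SamplerStats]
    seed: int
    meta: dict = field(default_factory=dict)
    _diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_chains(self) -> int:
        return self.draws_unconstrained.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws_unconstrained.shape[1]

    @property
    def divergences(self) -> int:
        return int(sum(s.divergences for s in self.sampler_stats))

    def to_inference_data(self) -> az.InferenceData:
        posterior = {k: v for k, v in self.posterior.items()}
        posterior["b"] = self.b_draws
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"subject": self.pointwise_loglik},
        )

    @property
    def diagnostics(self) -> pd.DataFrame:
        """Per-parameter R-hat, bulk ESS and MCMC-SE for every sampled scalar
        (random effects summarised by their worst R-hat / smallest ESS)."""
        if self._diagnostics is None:
            self._diagnostics = _compute_diagnostics(self)
        return self._diagnostics

    def max_rhat(self, scope: str = "all") -> float:
        """Largest R-hat.  scope="reported" restricts to the parameters a
        summary table reports (fixed effects, scales, correlations, tau_h);
        scope="all" additionally includes every per-subject random effect."""
        diag = self.diagnostics
        if scope == "reported":
            diag = diag.drop(index="b(worst)", errors="ignore")
        return float(np.nanmax(diag["rhat"].to_numpy()))

    def posterior_mean(self, name: str) -> float:
        return float(self.posterior[name].mean())

    def credible_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo = 0.5 * (1.0 - prob)
        q = np.quantile(self.posterior[name], [lo, 1.0 - lo])
        return float(q[0]), float(q[1])


def _natural_draws(context: ModelContext, draws: np.ndarray) -> tuple[dict, np.ndarray]:
    """Map unconstrained draws (chains, draws, dim) to named natural scalars."""
    chains, ndraw, _ = draws.shape
    names = context.fixed_names
    out = {nm: np.empty((chains, ndraw)) for nm in names}
    D = context.D
    # correlation entries on the natural scale
    corr_names = []
    if D > 1:
        for i in range(1, D):
            for j in range(i):
                corr_names.append(
                    f"rho_{context.re_labels[i][4:]}_{context.re_labels[j][4:]}"
                )
        for nm in corr_names:
            out[nm] = np.empty((chains, ndraw))
    b_draws = np.empty((chains, ndraw, context.N, D))
    for c in range(chains):
        for d in range(ndraw):
            nat = context.unpack(draws[c, d])
            natvec = context.natural_fixed_vector(draws[c, d])
            for nm, idx in zip(names, range(context.n_fixed)):
                out[nm][c, d] = natvec[idx]
            b_draws[c, d] = nat["b"]
            if D > 1:
                P = nat["P"]
                pos = 0
                for i in range(1, D):
                    for j in range(i):
                        out[corr_names[pos]][c, d] = P[i, j]
                        pos += 1
    # expose tau and tau_h on the natural scale
    sl = context.slices["log_tau"]
    for d_idx, lab in enumerate(context.re_labels):
        out[lab] = np.exp(draws[:, :, sl.start + d_idx])
    raw = draws[:, :, context.slices["tauh_raw"].start]
    out["tau_h"] = context.spec.priors.tau_h_scale / (1.0 + np.exp(-raw))
    return out, b_draws


def _compute_diagnostics(result: FitResult) -> pd.DataFrame:
    post = {k: v for k, v in result.posterior.items()}
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name in post:
        r = float(rhat[name].values) if result.n_chains > 1 else np.nan
        e = float(ess[name].values)
        sd = float(post[name].std(ddof=1))
        rows.append(
            dict(
                parameter=name,
                mean=float(post[name].mean()),
                sd=sd,
                ess=e,
                mcse=sd / np.sqrt(e) if e > 0 else np.nan,
                rhat=r,
            )
        )
    # random-effect innovations: summarise by the worst-mixing component
    b = result.b_draws  # (chains, draws, N, D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b_idata = az.from_dict(posterior={"b": b})
        b_rhat = az.rhat(b_idata)["b"].values if result.n_chains > 1 else np.nan
        b_ess = az.ess(b_idata)["b"].values
    rows.append(
        dict(
            parameter="b(worst)",
            mean=np.nan,
            sd=np.nan,
            ess=float(np.nanmin(b_ess)),
            mcse=np.nan,
            rhat=float(np.nanmax(b_rhat)) if result.n_chains > 1 else np.nan,
        )
    )
    return pd.DataFrame(rows).set_index("parameter")


def _initial_point(context: ModelContext, rng: np.random.Generator) -> np.ndarray:
    """Random initialisation in unconstrained space, kept small so the first
    log density is finite (the hazard is exponential in its predictors)."""
    u = 0.5 * (2.0 * rng.uniform(size=context.dim) - 1.0)
    u[context.slices["z"]] = 0.1 * rng.standard_normal(context.N * context.D)
    u[context.slices["log_tau"]] = np.log(0.5) + 0.2 * rng.standard_normal(context.D)
    # start the log baseline hazard near the crude event rate
    total_time = float(np.sum(context.T - context.entry))
    crude = max(float(context.delta.sum()), 0.5) / max(total_time, 1e-12)
    sl = context.slices["gamma_h0"]
    u[sl] = np.log(crude) + 0.1 * rng.standard_normal(sl.stop - sl.start)
    return u


def _posterior_mode(
    context: ModelContext, u0: np.ndarray, maxiter: int = 300
) -> np.ndarray:
    """Starting point for the chains: L-BFGS over the fixed effects only,
    with the random-effect innovations pinned at zero and the scale /
    correlation parameters held at their initial values.  Optimising the
    full hierarchy jointly would collapse onto the degenerate mode (tau
    inflating while z overfits); this restricted optimum lands inside the
    typical set, which is all warmup adaptation needs."""
    from scipy.optimize import minimize

    base = u0.copy()
    base[context.slices["z"]] = 0.0
    base[context.slices["log_tau"]] = np.log(0.5)
    if context.m_corr:
        base[context.slices["corr_raw"]] = 0.0
    free = np.zeros(context.dim, dtype=bool)
    for key in context.slices:
        if key not in ("z", "log_tau", "corr_raw"):
            free[context.slices[key]] = True
    idx = np.flatnonzero(free)

    def objective(v):
        u = base.copy()
        u[idx] = v
        lp, g = context.logp_and_grad(u)
        if not np.isfinite(lp):
            return 1e300, np.zeros_like(v)
        return -lp, -g[idx]

    res = minimize(
        objective,
        base[idx],
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=maxiter, maxcor=25),
    )
    out = base.copy()
    out[idx] = res.x
    lp, _ = context.logp_and_grad(out)
    return out if np.isfinite(lp) else u0


def fit(
    long_data: LongitudinalDataset,
    surv_data: SurvivalData,
    spec: ModelSpec | None = None,
    chains: int = 2,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    max_depth: int = 8,
    target_accept: float = 0.8,
    init: str = "mode",
) -> FitResult:
    """Sample the joint posterior; defaults follow common practice for this
    model class (2 chains, 1000 warmup + 1000 kept draws each).

    init: "mode" starts every chain at an L-BFGS approximation of the
    posterior mode plus a chain-specific jitter; "random" starts from the
    dispersed random initialisation.
    """
    if chains < 1:
        raise ValueError("need at least one chain")
    spec = spec or ModelSpec()
    context = ModelContext(long_data, surv_data, spec)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    mode = None
    if init == "mode":
        mode_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(chains + 1)[chains])
        mode = _posterior_mode(context, _initial_point(context, mode_rng))
    all_draws = np.empty((chains, draws, context.dim))
    stats = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        if mode is not None:
            u0 = mode + 0.05 * rng.standard_normal(context.dim)
            logp0, _ = context.logp_and_grad(u0)
        else:
            u0 = _initial_point(context, rng)
            logp0, _ = context.logp_and_grad(u0)
        tries = 0
        while not np.isfinite(logp0) and tries < 20:
            u0 = _initial_point(context, rng)
            logp0, _ = context.logp_and_grad(u0)
            tries += 1
        chain_draws, st = nuts_sample(
            context.logp_and_grad,
            u0,
            warmup,
            draws,
            rng,
            max_depth=max_depth,
            target_accept=target_accept,
            post_step=(
                context.interweave if spec.association in ("LP", "CV") else None
            ),
        )
        all_draws[c] = chain_draws
        stats.append(st)

    posterior, b_draws = _natural_draws(context, all_draws)
    pointwise = np.empty((chains, draws, context.N))
    for c in range(chains):
        for d in range(draws):
            pointwise[c, d] = context.pointwise_loglik(all_draws[c, d])

    result = FitResult(
        context=context,
        draws_unconstrained=all_draws,
        posterior=posterior,
        b_draws=b_draws,
        pointwise_loglik=pointwise,
        sampler_stats=stats,
        seed=seed,
        meta=dict(
            chains=chains,
            warmup=warmup,
            draws=draws,
            association=spec.association,
            max_depth=max_depth,
        ),
    )
    max_rhat = result.max_rhat() if chains > 1 else np.nan
    if np.isfinite(max_rhat) and max_rhat > RHAT_THRESHOLD:
        warnings.warn(
            f"convergence not reached: max R-hat {max_rhat:.3f} > {RHAT_THRESHOLD}",
            stacklevel=2,
        )
    return result


def fit_constant_variance(
    long_data: LongitudinalDataset,
    surv_data: SurvivalData,
    spec: ModelSpec | None = None,
    **kwargs,
) -> FitResult:
    """Fit the constant-variance comparator (standard joint model)."""
    if spec is None:
        cv_spec = ModelSpec.constant_variance(long_data.n_biomarkers)
    else:
        cv_spec = ModelSpec.constant_variance(
            long_data.n_biomarkers,
            design={k: v for k, v in (spec.design or {}).items() if k[0] == "mu"},
            association=spec.association,
            spline_basis=spec.spline_basis,
            spline_degree=spec.spline_degree,
            diff_order=spec.diff_order,
            q_nodes=spec.q_nodes,
            priors=spec.priors,
            center=spec.center,
        )
    return fit(long_data, surv_data, cv_spec, **kwargs)


def predict_survival(
    result: FitResult,
    subject_id,
    times: np.ndarray,
    prob: float = 0.95,
    thin: int = 1,
) -> dict:
    """Per-draw survival curves S_i(t) = exp(-CumHaz(entry_i, t)) using the
    subject's drawn random effects, with pointwise mean and credible band."""
    from .quadrature import integrate

    context = result.context
    i = context.subject_position(subject_id)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    entry = float(context.entry[i])
    lo_t, hi_t = context.spline.span
    if times.min() < entry or times.max() > hi_t:
        raise ValueError(
            f"prediction grid must lie within [entry={entry:g}, {hi_t:g}]"
        )
    flat = result.draws_unconstrained.reshape(-1, context.dim)[::thin]
    curves = np.empty((flat.shape[0], times.size))
    for d, u in enumerate(flat):
        nat = context.unpack(u)
        hazard = context.hazard_closure(nat, i)
        cum = np.array(
            [integrate(hazard, entry, t, context.rule) for t in times]
        )
        curves[d] = np.exp(-cum)
    lo = 0.5 * (1.0 - prob)
    return dict(
        times=times,
        curves=curves,
        mean=curves.mean(axis=0),
        lower=np.quantile(curves, lo, axis=0),
        upper=np.quantile(curves, 1.0 - lo, axis=0),
    )


def predict_trajectory(
    result: FitResult,
    subject_id,
    times: np.ndarray,
    biomarker: int = 1,
    z: float = 1.96,
    prob: float = 0.95,
    thin: int = 1,
) -> dict:
    """Posterior mean trajectory eta_mu_k(t) and the within-individual
    variability band eta_mu_k(t) +/- z * exp(eta_sigma_k(t))."""
    context = result.context
    i = context.subject_position(subject_id)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    flat = result.draws_unconstrained.reshape(-1, context.dim)[::thin]
    mu = np.empty((flat.shape[0], times.size))
    band_lo = np.empty_like(mu)
    band_hi = np.empty_like(mu)
    for d, u in enumerate(flat):
        nat = context.unpack(u)
        eta_mu, eta_sig = context.linear_predictors_at(nat, i, times)
        m = eta_mu[biomarker - 1]
        s = np.exp(eta_sig[biomarker - 1])
        mu[d] = m
        band_lo[d] = m - z * s
        band_hi[d] = m + z * s
    lo = 0.5 * (1.0 - prob)
    return dict(
        times=times,
        mean=mu.mean(axis=0),
        mean_lower=np.quantile(mu, lo, axis=0),
        mean_upper=np.quantile(mu, 1.0 - lo, axis=0),
        wiv_lower=band_lo.mean(axis=0),
        wiv_upper=band_hi.mean(axis=0),
    )


def summarise_fit(result: FitResult, hr_scale: float = 1.0) -> pd.DataFrame:
    """Posterior summary table: mean, MCMC-SE (SD / sqrt(ESS)), SD, 95%
    interval and R-hat per parameter; association and event coefficients
    also as hazard ratios exp(scale * coefficient)."""
    diag = result.diagnostics
    rows = []
    for name, draws in result.posterior.items():
        flat = draws.ravel()
        sd = float(flat.std(ddof=1))
        q025, q975 = np.quantile(flat, [0.025, 0.975])
        d = diag.loc[name] if name in diag.index else None
        mean_val = float(flat.mean())
        constant = sd <= 1e-12 * max(1.0, abs(mean_val))
        row = dict(
            parameter=name,
            mean=float(flat.mean()),
            mcse=np.nan if constant else (float(d["mcse"]) if d is not None else np.nan),
            sd=sd,
            q2_5=float(q025),
            q97_5=float(q975),
            rhat=np.nan if constant else (float(d["rhat"]) if d is not None else np.nan),
        )
        if name.startswith(("alpha", "gamma_")) and not name.startswith("gamma_h0"):
            row["hr"] = float(np.exp(hr_scale * row["mean"]))
            row["hr_2_5"] = float(np.exp(hr_scale * q025))
            row["hr_97_5"] = float(np.exp(hr_scale * q975))
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
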