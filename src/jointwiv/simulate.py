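"""Simulation from the Cox-Exponential joint model with LP association.

Each subject gets a 4-dimensional random-effect vector (random intercepts
for the mean and log-SD of two biomarkers), baseline covariates w1
(Bernoulli) and w2 (standard normal), an event time drawn by inverting the
cumulative hazard of

    h_i(t) = exp(log lambda + w_i' gamma + A_i + B t),

uniform censoring on (0, t_max), and biomarker values on a regular visit
schedule following the location-scale model with intercept + linear time
in both the mean and the log residual SD.

With linear-predictor (LP) association and intercept + time submodels, the
association term collapses into the subject-level intercept shift

    A_i = sum_k [a_mu_k (b0_mu_k + b_i_mu_k) + a_sig_k (b0_sig_k + b_i_sig_k)]

and the common slope

    B = sum_k [a_mu_k b1_mu_k + a_sig_k b1_sig_k],

so event times have the closed form implemented in ``invert_event_time``.
The default configuration is the simulation-study truth used throughout
the package's evaluation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import RandomEffectsCovariance
from .data import LongitudinalDataset, SurvivalData


def default_correlation() -> np.ndarray:
    """Random-effect correlations (order mu1, mu2, sigma1, sigma2):
    positive mean-mean correlation across biomarkers and positive
    mean-to-WIV correlation within each biomarker."""
    P = np.eye(4)
    P[0, 1] = P[1, 0] = 0.5  # mu1 - mu2
    P[0, 2] = P[2, 0] = 0.4  # mu1 - sigma1
    P[1, 3] = P[3, 1] = 0.4  # mu2 - sigma2
    return P


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the simulation-study truth."""

    n_subjects: int = 1000
    t_max: float = 10.0
    lambda0: float = 20.0
    w1_prob: float = 0.5
    gamma: tuple[float, float] = (0.930, -2.300)
    # association (alpha_mu1, alpha_sigma1, alpha_mu2, alpha_sigma2)
    alpha: tuple[float, float, float, float] = (-2.240, 1.900, 0.550, 0.350)
    # per biomarker: (intercept, time slope)
    beta_mu: tuple[tuple[float, float], ...] = ((2.190, -0.040), (1.040, 0.350))
    beta_sigma: tuple[tuple[float, float], ...] = ((-1.360, -0.020), (0.160, 0.010))
    # random-effect SDs in internal order (mu1, mu2, sigma1, sigma2)
    tau: tuple[float, float, float, float] = (0.810, 0.520, 0.440, 0.160)
    corr: np.ndarray = field(default_factory=default_correlation)
    visit_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        if self.t_max <= 0 or self.lambda0 <= 0 or self.visit_spacing <= 0:
            raise ValueError("t_max, lambda0 and visit_spacing must be positive")
        if not 0.0 <= self.w1_prob <= 1.0:
            raise ValueError("w1_prob must be a probability")
        if np.any(np.asarray(self.tau) < 0):
            raise ValueError("tau must be nonnegative")

    @property
    def n_biomarkers(self) -> int:
        return len(self.beta_mu)

    def covariance(self) -> RandomEffectsCovariance:
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau == 0):  # allow degenerate taus in the generator only
            tau = np.where(tau == 0, 1e-300, tau)
        return RandomEffectsCovariance(tau=tau, corr=self.corr)

    def truth(self) -> dict[str, float]:
        """Generating parameters keyed by the fitted-model parameter names."""
        out: dict[str, float] = {}
        K = self.n_biomarkers
        for k in range(1, K + 1):
            out[f"beta_mu{k}_intercept"] = self.beta_mu[k - 1][0]
            out[f"beta_mu{k}_time"] = self.beta_mu[k - 1][1]
            out[f"beta_sigma{k}_intercept"] = self.beta_sigma[k - 1][0]
            out[f"beta_sigma{k}_time"] = self.beta_sigma[k - 1][1]
        for lab, val in zip(("tau_mu1", "tau_mu2", "tau_sigma1", "tau_sigma2"), self.tau):
            out[lab] = val
        out["gamma_w1"] = self.gamma[0]
        out["gamma_w2"] = self.gamma[1]
        for j, (psi, k) in enumerate(
            [(p, k) for k in range(1, K + 1) for p in ("mu", "sigma")]
        ):
            out[f"alpha_{psi}{k}"] = self.alpha[j]
        return out


def draw_subject_frame(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Baseline covariates (w1 Bernoulli, w2 standard normal) and random
    effects b ~ N(0, T P T), one row per subject."""
    n = config.n_subjects
    w1 = rng.binomial(1, config.w1_prob, size=n).astype(float)
    w2 = rng.standard_normal(n)
    tau = np.asarray(config.tau, dtype=float)
    if np.all(tau == 0):
        b = np.zeros((n, tau.size))
    else:
        sigma = config.covariance().assemble()
        L = np.linalg.cholesky(sigma)
        b = rng.standard_normal((n, tau.size)) @ L.T
    return pd.DataFrame({"w1": w1, "w2": w2}), b


def linear_hazard_terms(
    config: SimulationConfig, b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-subject intercept A and common slope B of the log hazard."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    K = config.n_biomarkers
    a = np.asarray(config.alpha, dtype=float)
    A = np.zeros(b.shape[0])
    B = 0.0
    for k in range(K):
        a_mu, a_sig = a[2 * k], a[2 * k + 1]
        b_mu = b[:, k]  # internal order: mu blocks then sigma blocks
        b_sig = b[:, K + k]
        A += a_mu * (config.beta_mu[k][0] + b_mu) + a_sig * (
            config.beta_sigma[k][0] + b_sig
        )
        B += a_mu * config.beta_mu[k][1] + a_sig * config.beta_sigma[k][1]
    return A, float(B)


def invert_event_time(
    u: np.ndarray, config: SimulationConfig, A: np.ndarray, B: float, wgamma: np.ndarray
) -> np.ndarray:
    """Event times solving CumHaz(T) = -log u for the log-linear hazard.

    For B < 0 the cumulative hazard is bounded; draws beyond the bound
    never experience the event and return +inf (censored later).
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u > 1)):
        raise ValueError("u must lie in (0, 1]")
    rate = config.lambda0 * np.exp(np.asarray(wgamma, dtype=float) + np.asarray(A))
    if B == 0.0:
        return -np.log(u) / rate
    arg = 1.0 - B * np.log(u) / rate
    out = np.full(np.broadcast(u, arg).shape, np.inf)
    ok = arg > 0
    out[ok] = np.log(np.broadcast_to(arg, out.shape)[ok]) / B
    return out


def apply_censoring(
    T: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0, t_max) censoring: observed = min(T, T*), delta = 1{T <= T*}."""
    T = np.asarray(T, dtype=float)
    T_star = rng.uniform(0.0, config.t_max, size=T.shape)
    delta = (T <= T_star).astype(int)
    return np.minimum(T, T_star), delta


def generate_longitudinal(
    subject_id,
    observed_time: float,
    config: SimulationConfig,
    b_i: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Visits at 0, dt, 2dt, ... up to the observed time (always at least
    the t=0 visit); biomarker values from the location-scale model."""
    if observed_time < 0:
        raise ValueError("observed time must be nonnegative")
    n_vis = int(np.floor(observed_time / config.visit_spacing + 1e-9)) + 1
    times = np.arange(n_vis) * config.visit_spacing
    K = config.n_biomarkers
    rows = []
    for k in range(K):
        eta_mu = config.beta_mu[k][0] + b_i[k] + config.beta_mu[k][1] * times
        eta_sig = (
            config.beta_sigma[k][0] + b_i[K + k] + config.beta_sigma[k][1] * times
        )
        y = eta_mu + np.exp(eta_sig) * rng.standard_normal(times.size)
        rows.append(
            pd.DataFrame(
                {"id": subject_id, "time": times, "biomarker": k + 1, "value": y}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[LongitudinalDataset | None, SurvivalData | None, dict]:
    """Generate one joint dataset plus a truth record for recovery scoring.

    Returns (None, None, truth) for an empty configuration (N = 0).
    """
    rng = np.random.default_rng(config.seed)
    truth = dict(config.truth())
    truth_meta = dict(
        lambda0=config.lambda0,
        t_max=config.t_max,
        seed=config.seed,
        n_subjects=config.n_subjects,
    )
    if config.n_subjects == 0:
        return None, None, {**truth, "_meta": truth_meta}

    covs, b = draw_subject_frame(config, rng)
    A, B = linear_hazard_terms(config, b)
    wgamma = covs["w1"].to_numpy() * config.gamma[0] + covs["w2"].to_numpy() * config.gamma[1]
    u = rng.uniform(size=config.n_subjects)
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    T_event = invert_event_time(u, config, A, B, wgamma)
    observed, delta = apply_censoring(T_event, config, rng)

    surv = pd.DataFrame(
        {
            "id": np.arange(config.n_subjects),
            "entry": 0.0,
            "time": observed,
            "event": delta,
            "w1": covs["w1"],
            "w2": covs["w2"],
        }
    )
    long_frames = [
        generate_longitudinal(i, observed[i], config, b[i], rng)
        for i in range(config.n_subjects)
    ]
    long_df = pd.concat(long_frames, ignore_index=True)

    truth_meta.update(
        uniform_draws=u,
        random_effects=b,
        A=A,
        B=B,
        event_times=T_event,
    )
    return (
        LongitudinalDataset(long_df),
        SurvivalData(surv),
        {**truth, "_meta": truth_meta},
    )
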