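"""Prior configuration and log-density helpers.

Defaults: normal(0, 10) on the longitudinal fixed effects; normal(0, 2.5)
on event-submodel coefficients and association coefficients (the scale the
rstanarm joint model uses, which also keeps the weakly identified
association directions well conditioned for the sampler); half-t(3, 2.5)
on random-effect SDs; LKJ(1) on the correlation matrix; Beta(1, 1) on the
P-spline smoothing parameter tau_h, which lives in (0, 1).  All are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class NormalPrior:
    mean: float = 0.0
    sd: float = 10.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")


@dataclass(frozen=True)
class HalfTPrior:
    df: float = 3.0
    scale: float = 2.5

    def __post_init__(self) -> None:
        if self.df <= 0 or self.scale <= 0:
            raise ValueError("half-t df and scale must be positive")


@dataclass(frozen=True)
class BetaPrior:
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")


@dataclass(frozen=True)
class PriorConfig:
    beta_prior: NormalPrior = field(default_factory=NormalPrior)
    gamma_prior: NormalPrior = field(default_factory=lambda: NormalPrior(sd=2.5))
    alpha_prior: NormalPrior = field(default_factory=lambda: NormalPrior(sd=2.5))
    tau_prior: HalfTPrior = field(default_factory=HalfTPrior)
    lkj_eta: float = 1.0
    tau_h_prior: BetaPrior = field(default_factory=BetaPrior)
    # optional multiplier on tau_h for users needing stronger smoothing
    tau_h_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lkj_eta <= 0:
            raise ValueError("LKJ shape must be positive")
        if self.tau_h_scale <= 0:
            raise ValueError("tau_h multiplier must be positive")


def normal_logpdf_sum(x: np.ndarray, prior: NormalPrior) -> tuple[float, np.ndarray]:
    """Sum of normal log densities and its gradient (constants dropped)."""
    z = (np.asarray(x, dtype=float) - prior.mean) / prior.sd
    return float(-0.5 * np.sum(z * z)), -z / prior.sd


def half_t_log_terms(
    log_tau: np.ndarray, prior: HalfTPrior
) -> tuple[float, np.ndarray]:
    """Half-t log prior on tau evaluated on the log scale, including the
    log-tau change-of-variables term; returns (value, d/dlog_tau)."""
    tau = np.exp(np.asarray(log_tau, dtype=float))
    q = tau * tau / (prior.df * prior.scale**2)
    val = float(np.sum(-0.5 * (prior.df + 1.0) * np.log1p(q) + log_tau))
    grad = -(prior.df + 1.0) * q / (1.0 + q) + 1.0
    return val, grad
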