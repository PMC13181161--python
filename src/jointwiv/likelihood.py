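"""Per-observation and per-subject log-likelihood building blocks.

The longitudinal submodel is a mixed-effects location-scale model: for
biomarker k of subject i at time t,

    y ~ N(eta_mu(t), sigma(t)^2),   log sigma(t) = eta_sigma(t),

with both linear predictors of the form X beta + Z b.  The event submodel
is a proportional-hazards model whose log hazard adds the spline log
baseline, baseline covariate effects and an association term eta_alpha
driven by the longitudinal process (its current linear predictors, current
values, or random effects).

These closure-style functions are the reference implementations of the
likelihood; the fused vectorised versions used during sampling live in
``posterior`` and are tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import SurvivalRecord
from .design import DesignBlock
from .quadrature import QuadratureRule, default_rule
from .splines import BaselineHazardSpline

LOG_2PI = float(np.log(2.0 * np.pi))
_ETA_SIGMA_MAX = 350.0  # exp overflow guard


def linear_predictor(
    block: DesignBlock, beta: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """eta = X beta + Z b row-wise, each row using its own subject's b.

    ``b`` has one row per subject (survival-table order) and one column per
    random effect of this block; a 1-d ``b`` is treated as a single column.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size != block.n_fixed:
        raise ValueError(
            f"beta has {beta.size} entries, design has {block.n_fixed} columns"
        )
    eta = block.fixed_matrix @ beta
    if block.n_random:
        b = np.asarray(b, dtype=float)
        if b.ndim == 1:
            b = b[:, None]
        if b.shape[1] != block.n_random:
            raise ValueError(
                f"b has {b.shape[1]} columns, design has {block.n_random}"
            )
        eta = eta + np.sum(block.random_matrix * b[block.subject_index], axis=1)
    return eta


def residual_sd(eta_sigma: np.ndarray) -> np.ndarray:
    """sigma = exp(eta_sigma), overflow-guarded."""
    return np.exp(np.clip(np.asarray(eta_sigma, dtype=float), None, _ETA_SIGMA_MAX))


def longitudinal_loglik(
    y: np.ndarray, eta_mu: np.ndarray, eta_sigma: np.ndarray
) -> np.ndarray:
    """Per-observation Gaussian log density with log-linear residual SD."""
    y = np.asarray(y, dtype=float)
    eta_mu = np.asarray(eta_mu, dtype=float)
    eta_sigma = np.asarray(eta_sigma, dtype=float)
    if not (y.shape == eta_mu.shape == eta_sigma.shape):
        raise ValueError("y, eta_mu and eta_sigma must have equal length")
    r = y - eta_mu
    return -0.5 * LOG_2PI - eta_sigma - 0.5 * r * r * np.exp(-2.0 * eta_sigma)


@dataclass
class AssociationSpec:
    """How the longitudinal process enters the hazard.

    structure: "CV" (current values: mean and SD scale), "LP" (current
    linear predictors of mean and log SD) or "RE" (random effects).
    For CV/LP, ``alpha`` holds one (alpha_mu_k, alpha_sigma_k) pair per
    biomarker ordered (mu1, sigma1, mu2, sigma2, ...); entries for a
    submodel without association can be dropped via ``terms``.  For RE,
    one coefficient per random-effect component.
    """

    structure: str
    alpha: np.ndarray
    terms: tuple[tuple[str, int], ...] | None = None  # CV/LP only

    def __post_init__(self) -> None:
        if self.structure not in ("CV", "LP", "RE"):
            raise ValueError("structure must be one of CV, LP, RE")
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.structure in ("CV", "LP") and self.terms is not None:
            if len(self.terms) != self.alpha.size:
                raise ValueError("alpha length must match association terms")

    def resolved_terms(self, n_biomarkers: int) -> tuple[tuple[str, int], ...]:
        if self.structure == "RE":
            raise ValueError("RE association has no (psi, k) terms")
        if self.terms is not None:
            return self.terms
        terms = tuple(
            (psi, k) for k in range(1, n_biomarkers + 1) for psi in ("mu", "sigma")
        )
        if len(terms) != self.alpha.size:
            raise ValueError(
                f"alpha has {self.alpha.size} entries for {len(terms)} terms"
            )
        return terms


def association_predictor(
    spec: AssociationSpec,
    eta_mu: np.ndarray | None = None,
    eta_sigma: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> float:
    """eta_alpha for one subject at one time.

    eta_mu/eta_sigma are length-K vectors of the current linear predictors.
    """
    if spec.structure == "RE":
        if b is None:
            raise ValueError("RE association requires the random effects b")
        b = np.atleast_1d(np.asarray(b, dtype=float))
        if b.size != spec.alpha.size:
            raise ValueError("alpha length must match random-effect dimension")
        return float(spec.alpha @ b)
    if eta_mu is None or eta_sigma is None:
        raise ValueError(f"{spec.structure} association requires eta_mu and eta_sigma")
    eta_mu = np.atleast_1d(np.asarray(eta_mu, dtype=float))
    eta_sigma = np.atleast_1d(np.asarray(eta_sigma, dtype=float))
    K = eta_mu.size
    total = 0.0
    for coef, (psi, k) in zip(spec.alpha, spec.resolved_terms(K)):
        if psi == "mu":
            total += coef * eta_mu[k - 1]
        else:
            val = eta_sigma[k - 1]
            if spec.structure == "CV":
                val = np.exp(val)
            total += coef * val
    return float(total)


def hazard_at(
    t: float | np.ndarray,
    record: SurvivalRecord,
    spline: BaselineHazardSpline,
    gamma_event: np.ndarray,
    assoc: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """h_i(t) = exp(log h0(t) + w_i' gamma + eta_alpha(t)).

    ``assoc`` maps an array of times to the association predictor values
    for this subject (None means no association term).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    log_h = spline.log_baseline(t) + float(
        np.dot(record.covariates, np.atleast_1d(gamma_event))
    )
    if assoc is not None:
        log_h = log_h + np.asarray(assoc(t), dtype=float)
    return np.exp(np.clip(log_h, None, _ETA_SIGMA_MAX))


def cumulative_hazard(
    record: SurvivalRecord,
    hazard: Callable[[np.ndarray], np.ndarray],
    rule: QuadratureRule | None = None,
) -> float:
    """Gauss-Kronrod approximation of the integral of the hazard over the
    subject-specific at-risk interval [entry, T]."""
    rule = rule or default_rule()
    a, b = record.entry_time, record.observed_time
    if b < a:
        raise ValueError("entry time exceeds observed time")
    if a == b:
        return 0.0
    s, w = rule.mapped(a, b)
    return float(np.dot(w, np.asarray(hazard(s), dtype=float)))


def event_loglik(
    record: SurvivalRecord,
    hazard: Callable[[np.ndarray], np.ndarray],
    rule: QuadratureRule | None = None,
) -> float:
    """delta * log h(T) - integral of h over [entry, T]."""
    cum = cumulative_hazard(record, hazard, rule)
    if record.event:
        h_T = float(np.asarray(hazard(np.array([record.observed_time])))[0])
        return float(np.log(h_T) - cum)
    return -cum
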