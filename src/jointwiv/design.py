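"""Design matrices for the location (mu) and scale (sigma) submodels.

A design is described by a list of terms: ``"1"`` (intercept), ``"time"``
(the visit time), or the name of a subject-level baseline covariate taken
from the survival table.  This explicit-term form is what lets the event
submodel re-evaluate the same design at arbitrary quadrature node times
with the subject's covariates held fixed.

Baseline covariates are mean-centered by default (intercepts are then
reported on the centered scale); ``center=False`` disables this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, SurvivalData

DEFAULT_FIXED = ("1", "time")
DEFAULT_RANDOM = ("1",)


@dataclass
class DesignSpec:
    """Per-(submodel, biomarker) term lists."""

    fixed: tuple[str, ...] = DEFAULT_FIXED
    random: tuple[str, ...] = DEFAULT_RANDOM

    def __post_init__(self) -> None:
        self.fixed = tuple(self.fixed)
        self.random = tuple(self.random)
        if not self.fixed:
            raise ValueError("fixed design needs at least one term")


@dataclass
class DesignBlock:
    """Realised design for one (psi, k): matrices plus row bookkeeping."""

    fixed_matrix: np.ndarray
    random_matrix: np.ndarray
    submodel_tag: str  # "mu" or "sigma"
    biomarker_tag: int
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]
    subject_index: np.ndarray  # row -> subject position (survival-table order)
    centers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fixed_matrix.shape[0] != self.random_matrix.shape[0] and (
            self.random_matrix.size or self.random_matrix.shape[0]
        ):
            raise ValueError("fixed and random matrices disagree on row count")
        if self.submodel_tag not in ("mu", "sigma"):
            raise ValueError("submodel_tag must be 'mu' or 'sigma'")

    @property
    def n_fixed(self) -> int:
        return self.fixed_matrix.shape[1]

    @property
    def n_random(self) -> int:
        return self.random_matrix.shape[1]


def _term_columns(
    terms: tuple[str, ...],
    times: np.ndarray,
    covariates: pd.DataFrame | None,
    centers: dict[str, float],
) -> np.ndarray:
    """Evaluate terms at given times; covariates is one row per output row."""
    n = times.size
    cols = []
    for term in terms:
        if term == "1":
            cols.append(np.ones(n))
        elif term == "time":
            cols.append(np.asarray(times, dtype=float))
        else:
            if covariates is None or term not in covariates.columns:
                raise KeyError(f"unknown covariate {term!r} in design")
            cols.append(
                covariates[term].to_numpy(dtype=float) - centers.get(term, 0.0)
            )
    return np.column_stack(cols) if cols else np.empty((n, 0))


def covariate_centers(
    surv_data: SurvivalData, terms: set[str], center: bool
) -> dict[str, float]:
    if not center:
        return {}
    out = {}
    for term in terms:
        if term in ("1", "time"):
            continue
        if term in surv_data.table.columns:
            out[term] = float(surv_data.table[term].mean())
    return out


def build_designs(
    dataset: LongitudinalDataset,
    surv_data: SurvivalData,
    spec: dict[tuple[str, int], DesignSpec] | None = None,
    center: bool = True,
) -> dict[tuple[str, int], DesignBlock]:
    """One DesignBlock per (psi, k); default is intercept + linear time in X
    and an intercept-only Z for both submodels."""
    K = dataset.n_biomarkers
    spec = spec or {}
    subj_pos = {sid: i for i, sid in enumerate(surv_data.subject_ids)}
    surv_indexed = surv_data.table.set_index("id")

    all_terms: set[str] = set()
    specs: dict[tuple[str, int], DesignSpec] = {}
    for psi in ("mu", "sigma"):
        for k in range(1, K + 1):
            s = spec.get((psi, k), DesignSpec())
            specs[(psi, k)] = s
            all_terms |= set(s.fixed) | set(s.random)
    unknown = {
        t
        for t in all_terms
        if t not in ("1", "time") and t not in surv_data.table.columns
    }
    if unknown:
        raise KeyError(f"design references unknown covariates: {sorted(unknown)}")
    centers = covariate_centers(surv_data, all_terms, center)

    blocks: dict[tuple[str, int], DesignBlock] = {}
    for psi in ("mu", "sigma"):
        for k in range(1, K + 1):
            rows = dataset.for_biomarker(k)
            if len(rows) == 0:
                raise ValueError(f"no observations for biomarker {k}")
            times = rows["time"].to_numpy(dtype=float)
            covs = surv_indexed.loc[rows["id"]].reset_index()
            s = specs[(psi, k)]
            blocks[(psi, k)] = DesignBlock(
                fixed_matrix=_term_columns(s.fixed, times, covs, centers),
                random_matrix=_term_columns(s.random, times, covs, centers),
                submodel_tag=psi,
                biomarker_tag=k,
                fixed_terms=s.fixed,
                random_terms=s.random,
                subject_index=rows["id"].map(subj_pos).to_numpy(),
                centers=centers,
            )
    return blocks


def design_at_times(
    terms: tuple[str, ...],
    times: np.ndarray,
    subject_covariates: pd.Series | None,
    centers: dict[str, float],
) -> np.ndarray:
    """Evaluate a design for ONE subject at arbitrary times (used at
    quadrature nodes): time varies, covariates stay at the subject values."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    covs = (
        pd.DataFrame([subject_covariates] * times.size).reset_index(drop=True)
        if subject_covariates is not None
        else None
    )
    return _term_columns(terms, times, covs, centers)


def term_label(term: str) -> str:
    return "intercept" if term == "1" else term
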