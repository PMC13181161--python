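"""Simulation-study driver, coverage computation and PSIS-LOO comparison.

``run_simulation_study`` repeatedly simulates from the generator, fits the
requested models, and aggregates per-parameter posterior means, empirical
95% credible-interval coverage and ELPD into one table: for each parameter
it reports the truth, the mean and SD (eSD) of the replicate posterior
means, and the fraction of replicates whose interval contains the truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from .fit import FitResult, fit, fit_constant_variance
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

MODEL_FITTERS = {"wiv": fit, "constant_variance": fit_constant_variance}


def coverage(intervals, truth: float) -> float:
    """Fraction of (lower, upper) intervals containing the truth."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("coverage needs at least one interval")
    hits = sum(1 for lo, hi in intervals if lo <= truth <= hi)
    return hits / len(intervals)


@dataclass
class LooResult:
    elpd: float
    elpd_se: float
    pareto_k: np.ndarray

    def __post_init__(self) -> None:
        self.pareto_k = np.asarray(self.pareto_k, dtype=float)


def compute_loo(result: FitResult) -> LooResult:
    """PSIS-LOO expected log predictive density from the per-subject
    pointwise log-likelihood draws."""
    if result.pointwise_loglik.shape[-1] < 1:
        raise ValueError("pointwise log-likelihood is empty")
    idata = result.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(idata, pointwise=True)
    return LooResult(
        elpd=float(loo.elpd_loo),
        elpd_se=float(loo.se),
        pareto_k=np.asarray(loo.pareto_k),
    )


def loo_from_pointwise(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a (chains, draws, subjects) pointwise log-lik array."""
    pointwise_loglik = np.asarray(pointwise_loglik, dtype=float)
    if pointwise_loglik.ndim != 3:
        raise ValueError("expected a (chains, draws, subjects) array")
    idata = az.from_dict(log_likelihood={"subject": pointwise_loglik})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # no posterior group available: assume unit relative efficiency
        loo = az.loo(idata, pointwise=True, reff=1.0)
    return LooResult(
        elpd=float(loo.elpd_loo),
        elpd_se=float(loo.se),
        pareto_k=np.asarray(loo.pareto_k),
    )


@dataclass
class SimStudyResult:
    """Aggregated simulation-study output."""

    table: pd.DataFrame  # one row per (model, parameter)
    elpd: pd.DataFrame  # one row per (model, replicate)
    replicates: int
    failed: dict[str, list[int]]
    config: SimulationConfig
    raw_means: dict[str, pd.DataFrame] = field(default_factory=dict)
    raw_intervals: dict[str, dict[str, list[tuple[float, float]]]] = field(
        default_factory=dict
    )
    max_rhat: dict[str, float] = field(default_factory=dict)

    def parameter_row(self, model: str, parameter: str) -> pd.Series:
        return self.table.loc[(model, parameter)]

    def elpd_ordering_fraction(
        self, better: str = "wiv", worse: str = "constant_variance"
    ) -> float:
        """Fraction of replicates where ELPD(better) > ELPD(worse)."""
        a = self.elpd[self.elpd["model"] == better].set_index("replicate")["elpd"]
        b = self.elpd[self.elpd["model"] == worse].set_index("replicate")["elpd"]
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("no common replicates between the two models")
        return float((a[common] > b[common]).mean())


def run_simulation_study(
    config: SimulationConfig,
    replicates: int,
    models: tuple[str, ...] = ("wiv", "constant_variance"),
    mcmc: dict | None = None,
    base_seed: int = 0,
    compute_elpd: bool = True,
) -> SimStudyResult:
    """Simulate-fit-score loop; per-replicate seeds are base_seed + index so
    results are independent of execution order."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    mcmc = dict(mcmc or {})
    truth = config.truth()
    means: dict[str, list[dict]] = {m: [] for m in models}
    intervals: dict[str, dict[str, list]] = {
        m: {p: [] for p in truth} for m in models
    }
    elpd_rows = []
    failed: dict[str, list[int]] = {m: [] for m in models}
    max_rhat = {m: 0.0 for m in models}

    for r in range(replicates):
        cfg = replace(config, seed=base_seed + r)
        long_data, surv_data, _ = simulate_dataset(cfg)
        for model in models:
            fitter = MODEL_FITTERS[model]
            try:
                res = fitter(
                    long_data, surv_data, seed=base_seed + r, **mcmc
                )
            except Exception:
                logger.exception("replicate %d: %s fit failed", r, model)
                failed[model].append(r)
                continue
            row = {}
            for p in truth:
                if p in res.posterior:
                    row[p] = res.posterior_mean(p)
                    intervals[model][p].append(res.credible_interval(p))
            means[model].append(row)
            if res.n_chains > 1:
                max_rhat[model] = max(max_rhat[model], res.max_rhat())
            if compute_elpd:
                loo = compute_loo(res)
                elpd_rows.append(
                    dict(model=model, replicate=r, elpd=loo.elpd, se=loo.elpd_se)
                )

    rows = []
    raw_means = {}
    for model in models:
        df = pd.DataFrame(means[model])
        raw_means[model] = df
        for p, true_val in truth.items():
            if p not in df.columns or df[p].dropna().empty:
                continue
            vals = df[p].dropna().to_numpy()
            rows.append(
                dict(
                    model=model,
                    parameter=p,
                    truth=true_val,
                    mean=float(vals.mean()),
                    esd=float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    coverage=coverage(intervals[model][p], true_val),
                    n_replicates=int(vals.size),
                )
            )
    table = pd.DataFrame(rows).set_index(["model", "parameter"])
    return SimStudyResult(
        table=table,
        elpd=pd.DataFrame(elpd_rows, columns=["model", "replicate", "elpd", "se"]),
        replicates=replicates,
        failed=failed,
        config=config,
        raw_means=raw_means,
        raw_intervals=intervals,
        max_rhat=max_rhat,
    )
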