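"""Run configuration: YAML round-trip for model, prior and MCMC settings."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DesignSpec
from .posterior import ModelSpec
from .priors import BetaPrior, HalfTPrior, NormalPrior, PriorConfig


@dataclass
class McmcSettings:
    chains: int = 2
    warmup: int = 1000
    draws: int = 1000
    max_depth: int = 8
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class RunConfig:
    longitudinal_path: str = ""
    survival_path: str = ""
    model: ModelSpec = field(default_factory=ModelSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"


def _priors_from_dict(d: dict) -> PriorConfig:
    def normal(key):
        v = d.get(key, {})
        return NormalPrior(**v) if v else NormalPrior()

    tau = d.get("tau_prior", {})
    th = d.get("tau_h_prior", {})
    return PriorConfig(
        beta_prior=normal("beta_prior"),
        gamma_prior=normal("gamma_prior"),
        alpha_prior=normal("alpha_prior"),
        tau_prior=HalfTPrior(**tau) if tau else HalfTPrior(),
        lkj_eta=float(d.get("lkj_eta", 1.0)),
        tau_h_prior=BetaPrior(**th) if th else BetaPrior(),
        tau_h_scale=float(d.get("tau_h_scale", 1.0)),
    )


def _design_from_dict(d: dict) -> dict[tuple[str, int], DesignSpec]:
    out = {}
    for key, val in d.items():
        psi, k = key.rsplit("_", 1)
        out[(psi, int(k))] = DesignSpec(
            fixed=tuple(val.get("fixed", ("1", "time"))),
            random=tuple(val.get("random", ("1",))),
        )
    return out


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    model_raw = raw.get("model", {})
    spec = ModelSpec(
        design=_design_from_dict(model_raw.get("design", {})) or None,
        association=model_raw.get("association", "LP"),
        spline_basis=int(model_raw.get("spline_basis", 6)),
        spline_degree=int(model_raw.get("spline_degree", 3)),
        diff_order=int(model_raw.get("diff_order", 2)),
        q_nodes=int(model_raw.get("q_nodes", 15)),
        priors=_priors_from_dict(model_raw.get("priors", {})),
        center=bool(model_raw.get("center", True)),
    )
    mcmc = McmcSettings(**raw.get("mcmc", {}))
    return RunConfig(
        longitudinal_path=raw.get("longitudinal_path", ""),
        survival_path=raw.get("survival_path", ""),
        model=spec,
        mcmc=mcmc,
        output_dir=raw.get("output_dir", "."),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
    )
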