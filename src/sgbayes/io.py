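"""Config parsing, input readers and report writers.

Analysis configs are YAML with three blocks: ``data`` (either inline
subgroup records with ``hr``/``ci`` or ``estimate``/``se`` fields, or a
``file`` pointing at a two-row CSV), ``prior`` (family name plus
parameters, see :func:`parse_prior_config`) and ``mcmc`` settings, plus a
mandatory top-level ``seed`` and an optional list of population
proportions ``pi`` for the overall-effect summaries.  Design configs add
a ``design`` block (n_total, pi list, per-arm event rates, critical
value).  Reports are JSON with full provenance: input values, prior
family and parameters, settings, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_model import SubgroupEstimates
from .elicitation import ElicitationGrid
from .inference import (
    McmcSettings,
    OverallEffectSpec,
    overall_effect,
    mcmc_posterior,
    sign_probabilities,
    summarize,
    summarize_samples,
)
from .priors import (
    BivariateNormalPrior,
    DiscretePrior,
    JointPriorSpec,
    NormalPrior,
    RectifiedJointPrior,
    SpikeSlabPrior,
    apply_power_prior,
)
from .trial_design import (
    TrialDesignSpec,
    power_curve,
)

__all__ = [
    "AnalysisConfig",
    "read_estimates_csv",
    "parse_prior_config",
    "parse_design_configs",
    "run_analysis",
    "write_report",
]

logger = logging.getLogger("sgbayes")


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


# ---------------------------------------------------------------------------
# input readers


def read_estimates_csv(path) -> SubgroupEstimates:
    """Read subgroup estimates from a two-row CSV.

    Columns: ``subgroup`` (values B and C), optional ``label``, and either
    ``hr, ci_lo, ci_hi`` or ``estimate, se``.
    """
    df = pd.read_csv(path)
    _require("subgroup" in df.columns, "estimates CSV needs a 'subgroup' column")
    rows = {str(r["subgroup"]).strip(): r for _, r in df.iterrows()}
    _require(set(rows) == {"B", "C"},
             "estimates CSV must have exactly one row per subgroup B and C")
    return _estimates_from_records(
        {g: dict(rows[g]) for g in ("B", "C")}, cov_BC=0.0
    )


def _estimates_from_records(rec: dict, cov_BC: float) -> SubgroupEstimates:
    def one(g):
        r = rec[g]
        label = str(r.get("label", g))
        if "hr" in r and not pd.isna(r.get("hr", np.nan)):
            ci = r.get("ci", [r.get("ci_lo"), r.get("ci_hi")])
            from .core_model import log_effect_from_hr_ci

            est, se = log_effect_from_hr_ci(float(r["hr"]), float(ci[0]), float(ci[1]))
            return est, se, label
        _require("estimate" in r and "se" in r,
                 f"subgroup {g}: need hr/ci or estimate/se")
        return float(r["estimate"]), float(r["se"]), label

    eB, sB, lB = one("B")
    eC, sC, lC = one("C")
    return SubgroupEstimates(
        mu_hat_B=eB, mu_hat_C=eC, var_B=sB**2, var_C=sC**2,
        cov_BC=cov_BC, label_B=lB, label_C=lC,
    )


def parse_data_config(cfg: dict, base_dir: Optional[Path] = None) -> SubgroupEstimates:
    _require(isinstance(cfg, dict), "'data' block must be a mapping")
    cov_BC = float(cfg.get("cov_BC", 0.0))
    if "file" in cfg and cfg["file"]:
        path = Path(cfg["file"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        est = read_estimates_csv(path)
        return dataclasses.replace(est, cov_BC=cov_BC)
    _require("subgroups" in cfg, "'data' block needs 'file' or 'subgroups'")
    recs = {}
    for entry in cfg["subgroups"]:
        name = str(entry.get("name", entry.get("subgroup", ""))).strip()
        _require(name in ("B", "C"), f"subgroup name must be B or C, got {name!r}")
        recs[name] = entry
    _require(set(recs) == {"B", "C"}, "need exactly subgroups B and C")
    return _estimates_from_records(recs, cov_BC=cov_BC)


# ---------------------------------------------------------------------------
# prior configs


def _parse_normal(cfg: dict) -> NormalPrior:
    prior = NormalPrior(
        mean=float(cfg["mean"]), sd=float(cfg["sd"]),
        truncation_upper=(None if cfg.get("truncation_upper") is None
                          else float(cfg["truncation_upper"])),
    )
    if cfg.get("power_k") is not None:
        prior = apply_power_prior(prior, float(cfg["power_k"]))
    return prior


def parse_prior_config(cfg: dict, base_dir: Optional[Path] = None) -> JointPriorSpec:
    """Build a :class:`JointPriorSpec` from a prior config mapping."""
    _require(isinstance(cfg, dict), "'prior' block must be a mapping")
    param = cfg.get("parameterization", "muC_delta")
    if param == "muC_delta":
        _require("mu_C" in cfg and "delta" in cfg,
                 "muC_delta prior needs 'mu_C' and 'delta' blocks")
        mu_C = _parse_normal(cfg["mu_C"])
        dcfg = cfg["delta"]
        family = dcfg.get("family", "normal")
        if family == "normal":
            delta = _parse_normal(dcfg)
        elif family == "discrete":
            if "file" in dcfg:
                path = Path(dcfg["file"])
                if base_dir is not None and not path.is_absolute():
                    path = base_dir / path
                spec = json.loads(Path(path).read_text())
                delta = DiscretePrior(tuple(spec["values"]), tuple(spec["probs"]))
            else:
                delta = DiscretePrior(tuple(dcfg["values"]), tuple(dcfg["probs"]))
        elif family == "spike_slab":
            delta = SpikeSlabPrior(
                slab_sd=float(dcfg["slab_sd"]),
                spike_sd=float(dcfg.get("spike_sd", 0.01)),
            )
        else:
            raise ConfigError(f"unknown delta prior family {family!r}")
        return JointPriorSpec.independent(mu_C, delta)
    if param == "muB_muC":
        jcfg = cfg.get("joint")
        _require(isinstance(jcfg, dict), "muB_muC prior needs a 'joint' block")
        family = jcfg.get("family")
        if family == "bivariate_normal":
            mean = tuple(float(x) for x in jcfg["mean"])
            cov = tuple(tuple(float(x) for x in row) for row in jcfg["cov"])
            return JointPriorSpec.from_joint(BivariateNormalPrior(mean, cov))
        if family == "vague_bivariate_normal":
            return JointPriorSpec.from_joint(
                BivariateNormalPrior.vague(
                    variance=float(jcfg.get("variance", 100.0)),
                    correlation=float(jcfg.get("correlation", 0.5)),
                )
            )
        if family == "rectified":
            return JointPriorSpec.from_joint(
                RectifiedJointPrior(*(float(jcfg[k]) for k in "abcde"))
            )
        if family == "grid":
            path = Path(jcfg["file"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return JointPriorSpec.from_joint(ElicitationGrid.from_csv(path))
        raise ConfigError(f"unknown joint prior family {family!r}")
    raise ConfigError(f"unknown parameterization {param!r}")


def _parse_mcmc(cfg: Optional[dict], seed: int) -> McmcSettings:
    cfg = cfg or {}
    return McmcSettings(
        seed=seed,
        n_chains=int(cfg.get("chains", 2)),
        iterations_per_chain=int(cfg.get("iterations_per_chain", 50_000)),
        burn_in=int(cfg.get("burn_in", 20_000)),
        thin=int(cfg.get("thin", 2)),
    )


# ---------------------------------------------------------------------------
# analysis configuration and orchestration


@dataclass
class AnalysisConfig:
    """Validated end-to-end analysis configuration."""

    data: SubgroupEstimates
    prior: JointPriorSpec
    mcmc: McmcSettings
    pi_values: tuple[float, ...] = ()
    seed: int = 0
    provenance: dict = field(default_factory=dict)
    design: Optional[dict] = None

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Optional[Path] = None) -> "AnalysisConfig":
        _require(isinstance(raw, dict), "config must be a mapping")
        _require("seed" in raw and raw["seed"] is not None,
                 "a top-level 'seed' is mandatory for stochastic runs")
        seed = int(raw["seed"])
        _require("data" in raw, "config needs a 'data' block")
        data = parse_data_config(raw["data"], base_dir=base_dir)
        _require("prior" in raw, "config needs a 'prior' block")
        prior = parse_prior_config(raw["prior"], base_dir=base_dir)
        mcmc = _parse_mcmc(raw.get("mcmc"), seed)
        pi_values = tuple(float(p) for p in raw.get("pi", []))
        for p in pi_values:
            _require(0.0 <= p <= 1.0, f"pi value {p} outside [0, 1]")
        return cls(
            data=data, prior=prior, mcmc=mcmc, pi_values=pi_values,
            seed=seed, provenance={"config": raw}, design=raw.get("design"),
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        cfg = cls.from_dict(raw, base_dir=path.parent)
        cfg.provenance["config_path"] = str(path)
        return cfg


def parse_design_configs(raw: dict) -> list[TrialDesignSpec]:
    """Expand the 'design' block into one spec per requested pi."""
    _require(isinstance(raw, dict), "'design' block must be a mapping")
    pis = raw.get("pi")
    if isinstance(pis, (int, float)):
        pis = [pis]
    _require(bool(pis), "'design' block needs at least one pi")
    rates = raw.get("event_rates")
    _require(isinstance(rates, dict), "'design' block needs 'event_rates'")
    return [
        TrialDesignSpec(
            n_total=float(raw["n_total"]),
            pi=float(p),
            event_rate={g: dict(rates[g]) for g in ("B", "C")},
            crit=float(raw.get("crit", -1.96)),
        )
        for p in pis
    ]


def _summary_to_dict(summary) -> dict:
    out = {name: dict(s._asdict()) for name, s in summary.params.items()}
    for name, probs in summary.aux_probs.items():
        out[name] = {"category_probs": probs}
    return out


def run_analysis(config: AnalysisConfig) -> dict:
    """End-to-end analysis: infer, summarize, assemble a report dict.

    The report contains posterior summaries for mu_B, mu_C and delta, the
    overall effect mu_A for each requested population proportion pi, sign
    probabilities, auxiliary posteriors (slab indicator, category masses),
    convergence diagnostics, and full provenance.
    """
    logger.info("running MCMC: %s", config.mcmc)
    draws = mcmc_posterior(config.data, config.prior, config.mcmc)
    summary = summarize(draws)
    signs = sign_probabilities(draws)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "data": dataclasses.asdict(config.data),
        "prior": repr(config.prior),
        "mcmc": dataclasses.asdict(config.mcmc),
        "posterior": _summary_to_dict(summary),
        "sign_probabilities": dict(signs._asdict()),
        "diagnostics": draws.diagnostics,
    }
    overall = {}
    for p in config.pi_values:
        mu_A = overall_effect(draws, OverallEffectSpec(pi=p))
        overall[str(p)] = dict(summarize_samples(mu_A)._asdict())
    if overall:
        report["overall_effect_mu_A"] = overall
    if config.design is not None:
        specs = parse_design_configs(config.design)
        table = power_curve(draws, specs, seed=config.seed + 1)
        report["design"] = table.to_dict(orient="records")
    report["provenance"] = {
        k: v for k, v in config.provenance.items() if k != "config"
    }
    return report


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return super().default(obj)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, cls=_NumpyEncoder,
                                     default=str))
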