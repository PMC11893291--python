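"""Packaged example inputs.

Small fixtures used throughout the documentation and tests: the two
worked-example trials (subgroup hazard ratios with 95% CIs as published),
the informative priors motivated by companion trials, the elicited joint
probability grid, the 41-point uniform discrete prior for the interaction,
and the planned-trial design scenario.  Everything is stored as published
summaries (hazard ratios, probabilities, event rates); log-scale
quantities are derived at load time.
"""

from __future__ import annotations

import json
from importlib import resources

from .core_model import SubgroupEstimates
from .elicitation import ElicitationGrid, RegionPartition
from .io import read_estimates_csv
from .priors import DiscretePrior, NormalPrior, difference_prior_from_two_results
from .trial_design import TrialDesignSpec

__all__ = [
    "stampede_estimates",
    "meteor_estimates",
    "ryan_informative_muC_prior",
    "choueiri_delta_prior",
    "elicited_joint_grid",
    "default_partition",
    "discrete_delta_41",
    "design_scenario",
    "config_path",
]

_DATA = resources.files("sgbayes") / "data"


def _csv(name: str):
    with resources.as_file(_DATA / name) as path:
        return path


def stampede_estimates() -> SubgroupEstimates:
    """Prostate-cancer trial: non-metastatic (B) vs metastatic (C) subgroups.

    HR 0.75 (0.48, 1.18) in B and 0.61 (0.49, 0.75) in C, overall survival,
    combination therapy vs androgen-deprivation therapy alone.
    """
    with resources.as_file(_DATA / "stampede.csv") as p:
        return read_estimates_csv(p)


def meteor_estimates() -> SubgroupEstimates:
    """Renal-cell-cancer trial: with (B) vs without (C) bone metastases.

    HR 0.54 (0.34, 0.84) in B and 0.71 (0.55, 0.91) in C, overall
    survival, cabozantinib vs everolimus.
    """
    with resources.as_file(_DATA / "meteor.csv") as p:
        return read_estimates_csv(p)


def ryan_informative_muC_prior() -> NormalPrior:
    """Informative prior for mu_C from a companion metastatic-disease trial.

    HR 0.75 (0.61, 0.93) converted to the log scale: N(-0.288, 0.108^2).
    """
    from .core_model import log_effect_from_hr_ci

    est, se = log_effect_from_hr_ci(0.75, 0.61, 0.93)
    return NormalPrior(mean=est, sd=se)


def choueiri_delta_prior() -> NormalPrior:
    """Informative prior for delta from a companion renal-cell-cancer trial.

    Difference of log HRs 0.54 (0.32, 0.92) and 0.61 (0.41, 0.89) for the
    with/without bone-metastases subgroups, treated as independent:
    N(-0.122, 0.334^2).
    """
    return difference_prior_from_two_results(
        (0.54, (0.32, 0.92)), (0.61, (0.41, 0.89))
    )


def elicited_joint_grid() -> ElicitationGrid:
    """Elicited joint probability grid over hazard ratios 0.5 ... 1.0."""
    with resources.as_file(_DATA / "elicited_joint_grid.csv") as p:
        return ElicitationGrid.from_csv(p)


def default_partition() -> RegionPartition:
    """Region partition at hazard-ratio breakpoints 0.55 ... 0.95."""
    return RegionPartition.from_hr_breakpoints()


def discrete_delta_41() -> DiscretePrior:
    """Uniform discrete prior for delta on -2.0, -1.9, ..., 2.0."""
    spec = json.loads((_DATA / "discrete_delta_41.json").read_text())
    return DiscretePrior(tuple(spec["values"]), tuple(spec["probs"]))


def design_scenario(pi: float, n_total: float = 900.0) -> TrialDesignSpec:
    """Planned 900-patient follow-up trial to the renal-cell-cancer example.

    Two-year event rates 0.6/0.8 (active/control) in subgroup B and
    0.5/0.7 in subgroup C; 1:1 randomization within subgroups; the
    proportion pi recruited to subgroup B is the design choice under
    study.
    """
    return TrialDesignSpec(
        n_total=n_total,
        pi=pi,
        event_rate={
            "B": {"active": 0.6, "control": 0.8},
            "C": {"active": 0.5, "control": 0.7},
        },
    )


def config_path(name: str):
    """Filesystem path of a packaged example YAML config."""
    return _DATA / "configs" / name
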