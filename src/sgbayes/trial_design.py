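"""Designing a new two-subgroup trial from a posterior.

Given a posterior for (mu_B, mu_C) from an existing analysis, this module
predicts the operating characteristics of a planned trial in which a
proportion pi of the n_total patients is recruited to subgroup B with 1:1
randomization inside each subgroup:

1. expected event counts per subgroup analysis are patient numbers times
   per-arm event rates, and the variance of each log-hazard-ratio estimate
   is approximated as 4 / events (the standard approximation for a 1:1
   randomized survival comparison);
2. for each posterior draw, a future estimate is simulated,
   ``mu_hat_x_new ~ N(mu_x, sigma_x^2)``, the all-comer estimate is the
   pi-weighted average, and Z statistics are ``mu_hat_x_new / sigma_x``;
3. Bayesian Predictive Power (assurance) is the proportion of predictive Z
   draws below the critical value (default -1.96: benefit is a negative
   log hazard ratio), and gated conditional power restricts to draws
   already significant in the all-comer population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import PosteriorDraws

__all__ = [
    "TrialDesignSpec",
    "PredictedAnalysis",
    "PredictiveDraws",
    "predict_events",
    "predictive_draws",
    "bayesian_predictive_power",
    "conditional_power",
    "power_curve",
]


@dataclass(frozen=True)
class TrialDesignSpec:
    """A planned trial: size, subgroup split and per-arm event rates.

    ``event_rate`` maps subgroup ("B" or "C") to ``{"active": r, "control": r}``
    probabilities of an event within follow-up.  Randomization is 1:1
    within each subgroup.  Subgroup sizes ``n_total * pi`` may be
    non-integer; expected event counts are carried as reals throughout.
    """

    n_total: float
    pi: float
    event_rate: dict
    crit: float = -1.96

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        for grp in ("B", "C"):
            if grp not in self.event_rate:
                raise ValueError(f"event_rate missing subgroup {grp!r}")
            for arm in ("active", "control"):
                r = self.event_rate[grp].get(arm)
                if r is None or not 0.0 <= r <= 1.0:
                    raise ValueError(
                        f"event rate for {grp}/{arm} must lie in [0, 1]"
                    )

    @property
    def n_B(self) -> float:
        return self.n_total * self.pi

    @property
    def n_C(self) -> float:
        return self.n_total * (1.0 - self.pi)


@dataclass(frozen=True)
class PredictedAnalysis:
    """Predicted events and log-HR variances for the three analyses."""

    events_B: float
    events_C: float
    events_A: float
    sigma2_B: float
    sigma2_C: float
    sigma2_A: float

    @property
    def sigma_B(self) -> float:
        return math.sqrt(self.sigma2_B)

    @property
    def sigma_C(self) -> float:
        return math.sqrt(self.sigma2_C)

    @property
    def sigma_A(self) -> float:
        return math.sqrt(self.sigma2_A)


def predict_events(
    spec: TrialDesignSpec, sigma_A_method: str = "total_events"
) -> PredictedAnalysis:
    """Expected events per analysis and the implied variances.

    Each subgroup contributes ``n_subgroup * 1/2 * rate`` events per arm
    (the 1/2 reflecting 1:1 stratified randomization); the all-comer
    analysis pools both subgroups.  Variances are 4 / events.  With
    ``sigma_A_method="delta_method"`` the all-comer variance is instead
    ``pi^2 sigma_B^2 + (1 - pi)^2 sigma_C^2``, available for sensitivity
    analysis of the weighted-average approximation.
    """
    ev = {}
    for grp, n in (("B", spec.n_B), ("C", spec.n_C)):
        rates = spec.event_rate[grp]
        ev[grp] = n * 0.5 * rates["active"] + n * 0.5 * rates["control"]
    events_A = ev["B"] + ev["C"]
    for name, e in (("B", ev["B"]), ("C", ev["C"]), ("A", events_A)):
        if e <= 0:
            raise ValueError(
                f"zero predicted events in analysis {name}: variance undefined"
            )
    sigma2_B = 4.0 / ev["B"]
    sigma2_C = 4.0 / ev["C"]
    if sigma_A_method == "total_events":
        sigma2_A = 4.0 / events_A
    elif sigma_A_method == "delta_method":
        sigma2_A = spec.pi**2 * sigma2_B + (1.0 - spec.pi) ** 2 * sigma2_C
    else:
        raise ValueError("sigma_A_method must be 'total_events' or 'delta_method'")
    return PredictedAnalysis(
        events_B=ev["B"], events_C=ev["C"], events_A=events_A,
        sigma2_B=sigma2_B, sigma2_C=sigma2_C, sigma2_A=sigma2_A,
    )


@dataclass(frozen=True)
class PredictiveDraws:
    """Posterior-predictive future estimates and their Z statistics."""

    mu_hat_B_new: np.ndarray
    mu_hat_C_new: np.ndarray
    mu_hat_A_new: np.ndarray
    Z_B_new: np.ndarray
    Z_C_new: np.ndarray
    Z_A_new: np.ndarray
    pi: float
    analysis: PredictedAnalysis

    @property
    def n(self) -> int:
        return self.Z_A_new.size


def predictive_draws(
    posterior: PosteriorDraws,
    analysis: PredictedAnalysis,
    pi: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PredictiveDraws:
    """Simulate the planned trial's estimates from the posterior.

    For each retained posterior draw of (mu_B, mu_C), future subgroup
    estimates are drawn independently with the predicted variances; the
    all-comer estimate is the pi-weighted average.  The resulting draws
    blend posterior uncertainty about the true effects with the sampling
    noise of the new trial.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mu_B = posterior.mu_B.ravel()
    mu_C = posterior.mu_C.ravel()
    mB_new = rng.normal(mu_B, analysis.sigma_B)
    mC_new = rng.normal(mu_C, analysis.sigma_C)
    mA_new = pi * mB_new + (1.0 - pi) * mC_new
    return PredictiveDraws(
        mu_hat_B_new=mB_new,
        mu_hat_C_new=mC_new,
        mu_hat_A_new=mA_new,
        Z_B_new=mB_new / analysis.sigma_B,
        Z_C_new=mC_new / analysis.sigma_C,
        Z_A_new=mA_new / analysis.sigma_A,
        pi=pi,
        analysis=analysis,
    )


class BppResult(NamedTuple):
    BPP_A: float
    BPP_B: float
    BPP_C: float


def bayesian_predictive_power(
    draws: PredictiveDraws, crit: float = -1.96
) -> BppResult:
    """Proportion of predictive Z draws below the critical value.

    This is the assurance of the planned trial for each population: the
    posterior-predictive probability of a statistically significant result
    in the benefit direction.
    """
    return BppResult(
        BPP_A=float(np.mean(draws.Z_A_new < crit)),
        BPP_B=float(np.mean(draws.Z_B_new < crit)),
        BPP_C=float(np.mean(draws.Z_C_new < crit)),
    )


def conditional_power(
    draws: PredictiveDraws,
    gate: str,
    crit_gate: float = -1.96,
    crit_target: float = -1.96,
    min_gate_draws: int = 100,
) -> float:
    """Predictive power in a subgroup given significance in the all-comers.

    ``gate="B_given_A"`` estimates P(Z_B,new < crit_target | Z_A,new <
    crit_gate) as a proportion among the gate-passing predictive draws
    (mirroring a hierarchical test-B-only-if-A-significant strategy);
    similarly for ``"C_given_A"``.  Errors if fewer than
    ``min_gate_draws`` draws pass the gate (the estimate would be
    unstable).
    """
    targets = {"B_given_A": draws.Z_B_new, "C_given_A": draws.Z_C_new}
    if gate not in targets:
        raise ValueError("gate must be 'B_given_A' or 'C_given_A'")
    passed = draws.Z_A_new < crit_gate
    n_pass = int(passed.sum())
    if n_pass == 0:
        raise ValueError("no predictive draws pass the gate")
    if n_pass < min_gate_draws:
        raise ValueError(
            f"only {n_pass} gate-passing draws (< {min_gate_draws}): "
            "conditional power estimate would be unstable"
        )
    return float(np.mean(targets[gate][passed] < crit_target))


def power_curve(
    posterior: PosteriorDraws,
    designs: Sequence[TrialDesignSpec],
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Tabulate predicted events and BPPs across a grid of designs.

    All designs share the posterior; they typically differ only in pi (and
    hence in the implied event counts).  Returns one row per design with
    events, sigma^2 and BPP per population.
    """
    ss = np.random.SeedSequence(seed).spawn(len(designs))
    rows = []
    for spec, s in zip(designs, ss):
        analysis = predict_events(spec)
        pred = predictive_draws(
            posterior, analysis, spec.pi, rng=np.random.default_rng(s)
        )
        bpp = bayesian_predictive_power(pred, crit=spec.crit)
        rows.append(
            {
                "pi": spec.pi,
                "n_total": spec.n_total,
                "events_B": analysis.events_B,
                "events_C": analysis.events_C,
                "events_A": analysis.events_A,
                "sigma2_B": analysis.sigma2_B,
                "sigma2_C": analysis.sigma2_C,
                "sigma2_A": analysis.sigma2_A,
                "BPP_A": bpp.BPP_A,
                "BPP_B": bpp.BPP_B,
                "BPP_C": bpp.BPP_C,
            }
        )
    return pd.DataFrame(rows)
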