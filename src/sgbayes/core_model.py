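"""Observed-data model for two-subgroup treatment-effect analysis.

The data are two treatment-effect estimates on a log scale (log hazard
ratios in the worked examples), one per disjoint subgroup B and C, with a
fixed and known covariance matrix::

    (mu_hat_B, mu_hat_C) | (mu_B, mu_C)  ~  N((mu_B, mu_C), Sigma)

where ``Sigma = [[var_B, cov_BC], [cov_BC, var_C]]``.  The difference
``delta = mu_B - mu_C`` quantifies the treatment-by-subgroup interaction.
This module houses the data container, the likelihood, and conversion from
published hazard-ratio + confidence-interval summaries to the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SubgroupEstimates",
    "EffectConvention",
    "log_effect_from_hr_ci",
    "make_estimates_from_published",
    "likelihood_logdensity",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SubgroupEstimates:
    """Estimated log-scale treatment effects in subgroups B and C.

    Parameters
    ----------
    mu_hat_B, mu_hat_C
        Estimated effects (e.g. log hazard ratios) in the two subgroups.
    var_B, var_C
        Squared standard errors of the estimates; must be positive.
    cov_BC
        Covariance between the two estimators.  Zero when the subgroups are
        analysed separately (different patients contribute to each), which
        is the default; a nonzero value is accepted but never inferred.
    label_B, label_C
        Human-readable subgroup descriptions for reports.
    """

    mu_hat_B: float
    mu_hat_C: float
    var_B: float
    var_C: float
    cov_BC: float = 0.0
    label_B: str = "B"
    label_C: str = "C"

    def __post_init__(self) -> None:
        if not (self.var_B > 0 and self.var_C > 0):
            raise ValueError("var_B and var_C must be strictly positive")
        if self.cov_BC**2 > self.var_B * self.var_C:
            raise ValueError(
                "cov_BC^2 exceeds var_B * var_C: not a valid covariance matrix"
            )

    @property
    def se_B(self) -> float:
        return math.sqrt(self.var_B)

    @property
    def se_C(self) -> float:
        return math.sqrt(self.var_C)

    @property
    def y(self) -> np.ndarray:
        """Observation vector ``(mu_hat_B, mu_hat_C)``."""
        return np.array([self.mu_hat_B, self.mu_hat_C])

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.array(
            [[self.var_B, self.cov_BC], [self.cov_BC, self.var_C]]
        )


@dataclass(frozen=True)
class EffectConvention:
    """Metadata recording which sign of the effect means benefit.

    Kept as pure metadata: no internal sign flipping is ever performed, all
    arithmetic stays on the raw log scale.  The worked examples use
    ``negative_is_benefit`` (log hazard ratios below zero favour treatment).
    """

    benefit_direction: str = "negative_is_benefit"
    scale_name: str = "log hazard ratio"

    _ALLOWED = ("negative_is_benefit", "positive_is_benefit")

    def __post_init__(self) -> None:
        if self.benefit_direction not in self._ALLOWED:
            raise ValueError(
                f"benefit_direction must be one of {self._ALLOWED}"
            )


def _z_multiplier(level: float) -> float:
    # Exactly 1.96 for the conventional 95% level so that standard errors
    # derived from published intervals reproduce the usual arithmetic.
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if level == 0.95:
        return 1.96
    return float(stats.norm.ppf(0.5 + level / 2.0))


def log_effect_from_hr_ci(
    hr: float, ci_lo: float, ci_hi: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert a hazard ratio and its CI to a log-scale estimate and SE.

    The standard error is the length of the confidence interval on the log
    scale divided by twice the normal quantile (2 x 1.96 at the default 95%
    level).

    Returns
    -------
    (estimate, se)
        ``estimate = log(hr)`` and ``se = (log(ci_hi) - log(ci_lo)) / (2 z)``.
    """
    if min(hr, ci_lo, ci_hi) <= 0:
        raise ValueError("hazard ratio and CI endpoints must be positive")
    if not (ci_lo <= hr <= ci_hi):
        raise ValueError("require ci_lo <= hr <= ci_hi")
    if ci_lo == ci_hi:
        raise ValueError("degenerate interval: ci_lo == ci_hi gives zero variance")
    z = _z_multiplier(level)
    estimate = math.log(hr)
    se = (math.log(ci_hi) - math.log(ci_lo)) / (2.0 * z)
    return estimate, se


def make_estimates_from_published(
    hr_B: float,
    ci_B: tuple[float, float],
    hr_C: float,
    ci_C: tuple[float, float],
    cov_BC: float = 0.0,
    label_B: str = "B",
    label_C: str = "C",
    level: float = 0.95,
) -> SubgroupEstimates:
    """Build :class:`SubgroupEstimates` from published HR + 95% CI triples.

    The two subgroup estimators are treated as conditionally independent by
    default (``cov_BC = 0``), appropriate when the subgroups are analysed
    separately so that different patients contribute to each estimate.
    """
    est_B, se_B = log_effect_from_hr_ci(hr_B, ci_B[0], ci_B[1], level=level)
    est_C, se_C = log_effect_from_hr_ci(hr_C, ci_C[0], ci_C[1], level=level)
    return SubgroupEstimates(
        mu_hat_B=est_B,
        mu_hat_C=est_C,
        var_B=se_B**2,
        var_C=se_C**2,
        cov_BC=cov_BC,
        label_B=label_B,
        label_C=label_C,
    )


def likelihood_logdensity(
    data: SubgroupEstimates, mu_B: float, mu_C: float
) -> float:
    """Bivariate-normal log likelihood of the observed estimates.

    Evaluates the density of ``(mu_hat_B, mu_hat_C)`` at mean
    ``(mu_B, mu_C)`` with the data's fixed covariance matrix.  With
    ``cov_BC = 0`` this reduces to the sum of two univariate normal log
    densities.
    """
    var_B, var_C, cov = data.var_B, data.var_C, data.cov_BC
    det = var_B * var_C - cov * cov
    if det <= 0:
        raise ValueError("singular covariance matrix in likelihood")
    rB = data.mu_hat_B - mu_B
    rC = data.mu_hat_C - mu_C
    quad = (var_C * rB * rB - 2.0 * cov * rB * rC + var_B * rC * rC) / det
    return -_LOG_2PI - 0.5 * math.log(det) - 0.5 * quad
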