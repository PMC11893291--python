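"""Prior families for the two-subgroup model.

The model has three linearly dependent parameters (mu_B, mu_C and their
difference delta = mu_B - mu_C); a joint prior is specified for exactly two
of them and the third is implied.  Two parameterizations are supported:

* ``muC_delta`` -- independent priors on mu_C and delta.  This induces a
  positive prior association between mu_B and mu_C (Cov(mu_B, mu_C) =
  Var(mu_C)), encoding the notion that benefit in one subgroup makes
  benefit in the other more plausible, and permits shrinkage via an
  informative prior on delta.
* ``muB_muC`` -- one joint prior on (mu_B, mu_C): a correlated bivariate
  normal, a discrete elicitation grid, or the right-rectified-normal joint
  family (continuous on the negative half line with an atom at zero,
  expressing "harm is implausible and no effect has positive probability").

Supported component families for the ``muC_delta`` parameterization are
normal (optionally truncated above, optionally variance-inflated as a power
prior), discrete (categorical over a grid of candidate delta values, the
'chips and bins' style of elicitation) and spike-and-slab (a near-point
mass at zero mixed with a diffuse normal, with a uniform hyper-prior on the
mixing probability).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
from scipy import stats

from .core_model import log_effect_from_hr_ci

__all__ = [
    "NormalPrior",
    "PowerPriorSpec",
    "DiscretePrior",
    "SpikeSlabPrior",
    "BivariateNormalPrior",
    "RectifiedJointPrior",
    "JointPriorSpec",
    "apply_power_prior",
    "difference_prior_from_two_results",
    "spike_slab_slab_weight",
    "rectified_sample",
    "rectified_logpdf",
    "rectified_cdf",
    "prior_logdensity",
    "sample_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


# ---------------------------------------------------------------------------
# component priors


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior ``N(mean, sd^2)``, optionally truncated from above.

    With ``truncation_upper`` set, the density is renormalized to integrate
    to one over ``(-inf, truncation_upper]`` and sampling uses the inverse
    CDF, which is exact however far the bound sits in the tail.
    """

    mean: float
    sd: float
    truncation_upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def variance(self) -> float:
        return self.sd**2

    def _trunc_mass(self) -> float:
        # prior mass of the untruncated normal below the bound
        return float(
            stats.norm.cdf(self.truncation_upper, self.mean, self.sd)
        )

    def logpdf(self, x: float) -> float:
        if self.sd == 0:
            raise ValueError("point-mass prior has no density")
        if self.truncation_upper is not None and x > self.truncation_upper:
            return -math.inf
        lp = _norm_logpdf(x, self.mean, self.sd)
        if self.truncation_upper is not None:
            lp -= math.log(self._trunc_mass())
        return lp

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        if self.truncation_upper is None:
            return rng.normal(self.mean, self.sd, size=n)
        u = rng.uniform(0.0, self._trunc_mass(), size=n)
        return stats.norm.ppf(u, self.mean, self.sd)


@dataclass(frozen=True)
class PowerPriorSpec:
    """A normal prior discounted by a power ``k`` in (0, 1].

    The discounted prior keeps the mean and inflates the variance to
    ``sd^2 / k``; ``k = 1`` reproduces the base prior and smaller ``k``
    down-weights the historical information it encodes.
    """

    base: NormalPrior
    k: float

    def __post_init__(self) -> None:
        if not 0.0 < self.k <= 1.0:
            raise ValueError("power-prior k must lie in (0, 1]")

    def applied(self) -> NormalPrior:
        return apply_power_prior(self.base, self.k)


def apply_power_prior(base: NormalPrior, k: float) -> NormalPrior:
    """Discount a normal prior: same mean, variance divided by ``k``."""
    if not 0.0 < k <= 1.0:
        raise ValueError("power-prior k must lie in (0, 1]")
    return replace(base, sd=base.sd / math.sqrt(k))


@dataclass(frozen=True)
class DiscretePrior:
    """Categorical prior over candidate values ``d_j`` with weights ``p_j``.

    Implemented through a latent category indicator M with P(M = j) = p_j
    and delta = d_M, so the posterior over M (and hence over the candidate
    values) is itself a mass function.
    """

    values: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
        if len(self.values) != len(self.probs) or len(self.values) < 1:
            raise ValueError("values and probs must have equal length >= 1")
        if any(p < 0 for p in self.probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    def logpmf(self, x: float) -> float:
        for v, p in zip(self.values, self.probs):
            if x == v:
                return math.log(p) if p > 0 else -math.inf
        return -math.inf

    def sample_index(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(len(self.values), size=n, p=np.asarray(self.probs))


@dataclass(frozen=True)
class SpikeSlabPrior:
    """Spike-and-slab mixture prior for the subgroup difference.

    The spike is N(0, spike_sd^2) with spike_sd = 0.01 (variance 1e-4), a
    near-point mass at "no interaction"; the slab is N(0, slab_sd^2) with a
    user-chosen slab_sd (tau).  A latent Bernoulli R selects the component,
    with inclusion probability P given a uniform hyper-prior, so the prior
    inclusion probability of the slab is 1/2 marginally.
    """

    slab_sd: float
    spike_sd: float = 0.01
    inclusion_prior: str = "uniform_P"

    def __post_init__(self) -> None:
        if self.slab_sd <= 0 or self.spike_sd <= 0:
            raise ValueError("spike and slab standard deviations must be positive")
        if self.inclusion_prior != "uniform_P":
            raise ValueError("only the uniform hyper-prior on P is supported")
        if self.slab_sd <= 10.0 * self.spike_sd:
            warnings.warn(
                "slab sd is not much larger than spike sd; the mixture "
                "components are poorly separated",
                stacklevel=2,
            )

    def logpdf_marginal(self, x: float) -> float:
        # marginal over (P, R): prior inclusion probability is E[P] = 1/2
        a = _norm_logpdf(x, 0.0, self.spike_sd)
        b = _norm_logpdf(x, 0.0, self.slab_sd)
        m = max(a, b)
        return m + math.log(0.5 * math.exp(a - m) + 0.5 * math.exp(b - m))


@dataclass(frozen=True)
class BivariateNormalPrior:
    """Joint normal prior for (mu_B, mu_C) with general covariance.

    The vague version is centred at the origin with equal large marginal
    variances (100, say) and correlation 0.5, which gives all three of
    mu_B, mu_C and delta the same vague marginal prior.
    """

    mean: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        c = self.cov_matrix
        if abs(c[0, 1] - c[1, 0]) > 1e-12:
            raise ValueError("covariance matrix must be symmetric")
        if c[0, 0] <= 0 or np.linalg.det(c) <= 0:
            raise ValueError("covariance matrix must be positive definite")

    @classmethod
    def vague(cls, variance: float = 100.0, correlation: float = 0.5):
        cov = variance * correlation
        return cls((0.0, 0.0), ((variance, cov), (cov, variance)))

    @property
    def mean_vector(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.asarray(self.cov, dtype=float)

    def logpdf(self, mu_B: float, mu_C: float) -> float:
        return float(
            stats.multivariate_normal.logpdf(
                [mu_B, mu_C], self.mean_vector, self.cov_matrix
            )
        )

    def sample(self, n: int, rng: np.random.Generator):
        draws = rng.multivariate_normal(
            self.mean_vector, self.cov_matrix, size=n, method="svd"
        )
        return draws[:, 0], draws[:, 1]


# ---------------------------------------------------------------------------
# right-rectified normal family


def rectified_cdf(x: float, mu: float, sd: float) -> float:
    """CDF of Z = min(0, Y) for Y ~ N(mu, sd^2)."""
    if x >= 0:
        return 1.0
    return float(stats.norm.cdf(x, mu, sd))


def rectified_logpdf(x: float, mu: float, sd: float) -> float:
    """Log density of the right-rectified normal w.r.t. its mixed measure.

    For x < 0 this is the normal log density; at x = 0 it is the log of the
    atom mass 1 - Phi(-mu/sd); positive x has no support.
    """
    if x > 0:
        return -math.inf
    if x == 0:
        atom = 1.0 - float(stats.norm.cdf(-mu / sd))
        return math.log(atom) if atom > 0 else -math.inf
    return _norm_logpdf(x, mu, sd)


def rectified_sample(
    mu: float,
    sd: float,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw from the right-rectified normal: min(0, N(mu, sd^2))."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.minimum(0.0, rng.normal(mu, sd, size=n))


@dataclass(frozen=True)
class RectifiedJointPrior:
    """Joint prior built from right-rectified normals.

    The marginal is ``mu_C ~ RN(a, b^2)`` (point mass at zero of
    ``1 - Phi(-a/b)``), and conditionally
    ``mu_B | mu_C ~ RN(c * mu_C, max(d^2 + e * mu_C, 0))``: the conditional
    mean and variance of mu_B both depend on mu_C.  When the conditional
    variance hits zero, the conditional collapses to a point mass at
    ``min(0, c * mu_C)`` (the continuous limit of the rectified normal).
    """

    a: float
    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if self.b <= 0 or self.d <= 0:
            raise ValueError("scale constants b and d must be positive")

    @property
    def atom_mass_muC(self) -> float:
        return 1.0 - float(stats.norm.cdf(-self.a / self.b))

    def conditional_mean(self, mu_C: float) -> float:
        return self.c * mu_C

    def conditional_var(self, mu_C: float) -> float:
        return max(self.d**2 + self.e * mu_C, 0.0)

    def logpdf(self, mu_B: float, mu_C: float) -> float:
        lp = rectified_logpdf(mu_C, self.a, self.b)
        if lp == -math.inf:
            return -math.inf
        v = self.conditional_var(mu_C)
        if v == 0.0:
            point = min(0.0, self.conditional_mean(mu_C))
            return lp if mu_B == point else -math.inf
        return lp + rectified_logpdf(
            mu_B, self.conditional_mean(mu_C), math.sqrt(v)
        )

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        mu_C = rectified_sample(self.a, self.b, n, rng=rng)
        mean = self.c * mu_C
        var = np.maximum(self.d**2 + self.e * mu_C, 0.0)
        mu_B = np.minimum(0.0, rng.normal(mean, np.sqrt(var)))
        return mu_B, mu_C


# ---------------------------------------------------------------------------
# unified joint prior specification

DeltaPrior = Union[NormalPrior, DiscretePrior, SpikeSlabPrior]
JointPrior = Union[BivariateNormalPrior, RectifiedJointPrior, "ElicitationGridLike"]


@dataclass(frozen=True)
class JointPriorSpec:
    """A joint prior over two of the three parameters (mu_B, mu_C, delta).

    Either independent component priors for (mu_C, delta), or a single
    joint prior object for (mu_B, mu_C).  The third parameter is always
    defined by the identity delta = mu_B - mu_C.
    """

    parameterization: str
    mu_C: Optional[NormalPrior] = None
    delta: Optional[DeltaPrior] = None
    joint: Optional[object] = None

    def __post_init__(self) -> None:
        if self.parameterization == "muC_delta":
            if self.mu_C is None or self.delta is None:
                raise ValueError(
                    "muC_delta parameterization needs mu_C and delta priors"
                )
            if self.joint is not None:
                raise ValueError("muC_delta parameterization takes no joint prior")
        elif self.parameterization == "muB_muC":
            if self.joint is None:
                raise ValueError("muB_muC parameterization needs a joint prior")
            if self.mu_C is not None or self.delta is not None:
                raise ValueError(
                    "muB_muC parameterization takes only the joint prior"
                )
        else:
            raise ValueError(
                "parameterization must be 'muC_delta' or 'muB_muC'"
            )

    @classmethod
    def independent(cls, mu_C: NormalPrior, delta: DeltaPrior) -> "JointPriorSpec":
        return cls("muC_delta", mu_C=mu_C, delta=delta)

    @classmethod
    def from_joint(cls, joint: object) -> "JointPriorSpec":
        return cls("muB_muC", joint=joint)

    @classmethod
    def vague(cls, sd: float = 10.0) -> "JointPriorSpec":
        """Vague spec: mu_C ~ N(0, sd^2) and delta ~ N(0, sd^2)."""
        return cls.independent(NormalPrior(0.0, sd), NormalPrior(0.0, sd))


def prior_logdensity(spec: JointPriorSpec, mu_B: float, mu_C: float) -> float:
    """Joint log prior density (or log mass) at (mu_B, mu_C).

    For the muC_delta parameterization the density is evaluated through
    delta = mu_B - mu_C; -inf outside the support (above a truncation
    bound, off a discrete grid, or on the positive axis for rectified
    components without an atom there).
    """
    if spec.parameterization == "muC_delta":
        delta = mu_B - mu_C
        lp_c = spec.mu_C.logpdf(mu_C)
        if isinstance(spec.delta, NormalPrior):
            lp_d = spec.delta.logpdf(delta)
        elif isinstance(spec.delta, DiscretePrior):
            lp_d = spec.delta.logpmf(delta)
        elif isinstance(spec.delta, SpikeSlabPrior):
            lp_d = spec.delta.logpdf_marginal(delta)
        else:  # pragma: no cover - guarded by the dataclass validation
            raise TypeError(f"unsupported delta prior {type(spec.delta)}")
        return lp_c + lp_d
    joint = spec.joint
    if hasattr(joint, "logpdf"):
        return float(joint.logpdf(mu_B, mu_C))
    # discrete elicitation grid
    return float(joint.log_joint_mass(mu_B, mu_C))


def sample_prior(
    spec: JointPriorSpec, n: int, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, np.ndarray]:
    """Draw n independent samples of (mu_B, mu_C, delta) from the prior.

    delta = mu_B - mu_C holds exactly for every draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.parameterization == "muC_delta":
        mu_C = spec.mu_C.sample(n, rng)
        if isinstance(spec.delta, NormalPrior):
            delta = spec.delta.sample(n, rng)
        elif isinstance(spec.delta, DiscretePrior):
            idx = spec.delta.sample_index(n, rng)
            delta = np.asarray(spec.delta.values)[idx]
        elif isinstance(spec.delta, SpikeSlabPrior):
            p = rng.uniform(size=n)
            r = rng.uniform(size=n) < p
            sd = np.where(r, spec.delta.slab_sd, spec.delta.spike_sd)
            delta = rng.normal(0.0, sd)
        else:  # pragma: no cover
            raise TypeError(f"unsupported delta prior {type(spec.delta)}")
        mu_B = mu_C + delta
    else:
        joint = spec.joint
        if hasattr(joint, "sample"):
            mu_B, mu_C = joint.sample(n, rng)
        else:
            mu_B, mu_C = joint.sample_joint(n, rng)
    # recompute so the identity is exact in floating point
    delta = mu_B - mu_C
    return {"mu_B": np.asarray(mu_B, dtype=float),
            "mu_C": np.asarray(mu_C, dtype=float),
            "delta": np.asarray(delta, dtype=float)}


# ---------------------------------------------------------------------------
# derived constructions


def difference_prior_from_two_results(
    res1: tuple[float, tuple[float, float]],
    res2: tuple[float, tuple[float, float]],
) -> NormalPrior:
    """Normal prior for a log-scale difference of two published results.

    Each result is an ``(hr, (ci_lo, ci_hi))`` pair.  The prior mean is the
    difference of the log hazard ratios and the variance is the sum of the
    two squared standard errors (the results are taken as independent).
    """
    hr1, ci1 = res1
    hr2, ci2 = res2
    est1, se1 = log_effect_from_hr_ci(hr1, ci1[0], ci1[1])
    est2, se2 = log_effect_from_hr_ci(hr2, ci2[0], ci2[1])
    return NormalPrior(mean=est1 - est2, sd=math.hypot(se1, se2))


def spike_slab_slab_weight(
    delta_hat: float,
    var_delta_hat: float,
    tau2: float,
    spike_var: float = 0.0001,
    prior_slab_weight: float = 0.5,
) -> float:
    """Posterior slab weight in the collapsed spike-and-slab setting.

    In the simplified setting where only the estimate ``delta_hat`` with
    sampling variance ``v`` enters the analysis, the posterior of delta is
    a two-component mixture whose slab weight is the marginal-likelihood
    ratio::

        w = p N(delta_hat; 0, tau2 + v)
            / [p N(delta_hat; 0, tau2 + v) + (1-p) N(delta_hat; 0, s2 + v)]

    The weight tends to zero as tau2 grows, so a vague slab is dominated by
    the spike regardless of the data.  Used as an analytic oracle for the
    MCMC slab-inclusion rate.
    """
    if var_delta_hat <= 0 or tau2 <= 0 or spike_var <= 0:
        raise ValueError("variances must be positive")
    if not 0.0 < prior_slab_weight < 1.0:
        raise ValueError("prior_slab_weight must lie in (0, 1)")
    l_slab = _norm_logpdf(delta_hat, 0.0, math.sqrt(tau2 + var_delta_hat))
    l_spike = _norm_logpdf(delta_hat, 0.0, math.sqrt(spike_var + var_delta_hat))
    log_odds = (
        math.log(prior_slab_weight)
        - math.log1p(-prior_slab_weight)
        + l_slab
        - l_spike
    )
    return 1.0 / (1.0 + math.exp(-log_odds))
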