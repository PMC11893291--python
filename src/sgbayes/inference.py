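"""Posterior computation for the two-subgroup model.

Two routes to the posterior of (mu_B, mu_C, delta):

* :func:`conjugate_posterior` -- exact multivariate normal-normal update
  for independent (possibly degenerate) normal priors on mu_C and delta,
  and :func:`conjugate_posterior_bivariate` for a joint normal prior on
  (mu_B, mu_C).  These serve both as fast analysis paths and as oracles
  for the sampler.
* :func:`mcmc_posterior` -- bespoke Gibbs / Metropolis-within-Gibbs for
  every supported prior family.  All conditionals are closed-form or
  one-dimensional: normal components use exact conditional normals
  (truncated where bounded, via the inverse CDF), the discrete-prior
  category is drawn from its closed-form categorical conditional, the
  spike-and-slab indicator uses a collapsed marginal-likelihood update
  (integrating delta analytically, which avoids the mixing pathology of
  naive samplers at large slab variance), and the rectified joint prior is
  handled by random-walk Metropolis on the latent unrectified variables.

Summaries report posterior means, standard deviations, equal-tailed 95%
credible intervals and sign probabilities; split-Rhat and effective sample
sizes are attached as diagnostics, with a warning above 1.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .core_model import SubgroupEstimates
from .priors import (
    BivariateNormalPrior,
    DiscretePrior,
    JointPriorSpec,
    NormalPrior,
    RectifiedJointPrior,
    SpikeSlabPrior,
)

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "ParamSummary",
    "PosteriorSummary",
    "OverallEffectSpec",
    "GaussianPosterior",
    "conjugate_posterior",
    "conjugate_posterior_bivariate",
    "mcmc_posterior",
    "summarize",
    "summarize_samples",
    "overall_effect",
    "sign_probabilities",
]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile


# ---------------------------------------------------------------------------
# settings and containers


@dataclass(frozen=True)
class McmcSettings:
    """Sampler run configuration.

    Defaults mirror a conventional desk-scale analysis: two chains of
    50,000 iterations each, thinning of 2, burn-in of 20,000.
    """

    seed: int
    n_chains: int = 2
    iterations_per_chain: int = 50_000
    thin: int = 2
    burn_in: int = 20_000

    def __post_init__(self) -> None:
        if min(self.n_chains, self.iterations_per_chain, self.thin) < 1:
            raise ValueError("chains, iterations and thin must be positive")
        if self.burn_in < 0 or self.burn_in >= self.iterations_per_chain:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")

    @classmethod
    def quick(cls, seed: int, iterations_per_chain: int = 6_000,
              burn_in: int = 1_000, thin: int = 1, n_chains: int = 2):
        """Reduced settings for fast exploratory runs and test suites."""
        return cls(seed=seed, n_chains=n_chains,
                   iterations_per_chain=iterations_per_chain,
                   burn_in=burn_in, thin=thin)

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations_per_chain - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Joint posterior draws of (mu_B, mu_C, delta) with chain structure.

    Arrays are shaped ``(n_chains, n_retained)``.  ``delta`` satisfies
    ``delta == mu_B - mu_C`` exactly (in floating point) for every draw.
    ``aux`` holds optional latent-variable traces aligned 1:1 with the
    parameter draws: ``M`` (discrete-prior category), ``R`` (slab
    indicator) and ``P`` (slab inclusion probability).
    """

    mu_B: np.ndarray
    mu_C: np.ndarray
    delta: np.ndarray
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu_B = np.atleast_2d(np.asarray(self.mu_B, dtype=float))
        self.mu_C = np.atleast_2d(np.asarray(self.mu_C, dtype=float))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        if not (self.mu_B.shape == self.mu_C.shape == self.delta.shape):
            raise ValueError("draw arrays must share one shape")
        for name, arr in self.aux.items():
            if np.atleast_2d(arr).shape != self.mu_B.shape:
                raise ValueError(f"aux sequence {name!r} misaligned with draws")
        if not np.array_equal(self.delta, self.mu_B - self.mu_C):
            raise ValueError("delta must equal mu_B - mu_C exactly per draw")

    @classmethod
    def from_mu_C_delta(cls, mu_C: np.ndarray, delta: np.ndarray,
                        **kwargs) -> "PosteriorDraws":
        mu_C = np.atleast_2d(np.asarray(mu_C, dtype=float))
        mu_B = mu_C + np.atleast_2d(np.asarray(delta, dtype=float))
        return cls(mu_B=mu_B, mu_C=mu_C, delta=mu_B - mu_C, **kwargs)

    @property
    def n_total(self) -> int:
        return self.mu_B.size

    def flat(self, name: str) -> np.ndarray:
        if name in ("mu_B", "mu_C", "delta"):
            return getattr(self, name).ravel()
        return np.atleast_2d(self.aux[name]).ravel()


class ParamSummary(NamedTuple):
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float
    prob_below_0: float
    flagged: bool = False


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior summaries plus auxiliary category masses."""

    params: dict[str, ParamSummary]
    aux_probs: dict[str, dict[int, float]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> ParamSummary:
        return self.params[name]


@dataclass(frozen=True)
class OverallEffectSpec:
    """Proportion pi of subgroup-B patients in the target population."""

    pi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")


# ---------------------------------------------------------------------------
# conjugate closed forms


def _gaussian_update(y, Sigma, X, offset, m0, V0):
    """Posterior N(m, V) of theta given y ~ N(X theta + offset, Sigma)."""
    Lam = np.linalg.inv(Sigma)
    P0 = np.linalg.inv(V0)
    P = P0 + X.T @ Lam @ X
    V = np.linalg.inv(P)
    m = V @ (P0 @ m0 + X.T @ Lam @ (y - offset))
    return m, V


@dataclass(frozen=True)
class GaussianPosterior:
    """Exact joint normal posterior over (mu_C, delta).

    ``mean`` and ``cov`` are in the (mu_C, delta) parameterization; a zero
    row/column in ``cov`` marks a parameter fixed by a point-mass prior.
    Marginals for mu_B follow from mu_B = mu_C + delta.
    """

    mean: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]

    @property
    def mean_vector(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.asarray(self.cov, dtype=float)

    def marginal(self, name: str) -> tuple[float, float]:
        """(mean, sd) of one of 'mu_C', 'delta', 'mu_B'."""
        m = self.mean_vector
        V = self.cov_matrix
        if name == "mu_C":
            return float(m[0]), math.sqrt(max(V[0, 0], 0.0))
        if name == "delta":
            return float(m[1]), math.sqrt(max(V[1, 1], 0.0))
        if name == "mu_B":
            var = V[0, 0] + V[1, 1] + 2.0 * V[0, 1]
            return float(m[0] + m[1]), math.sqrt(max(var, 0.0))
        raise KeyError(name)

    def prob_below_zero(self, name: str) -> float:
        mean, sd = self.marginal(name)
        if sd == 0.0:
            return 1.0 if mean < 0 else 0.0
        return float(ndtr(-mean / sd))

    def summary(self) -> PosteriorSummary:
        params = {}
        for name in ("mu_B", "mu_C", "delta"):
            mean, sd = self.marginal(name)
            params[name] = ParamSummary(
                mean=mean, sd=sd,
                ci_lo=mean - _Z975 * sd, ci_hi=mean + _Z975 * sd,
                prob_below_0=self.prob_below_zero(name),
            )
        return PosteriorSummary(params=params)

    def sample(self, n: int, rng: np.random.Generator) -> PosteriorDraws:
        draws = rng.multivariate_normal(
            self.mean_vector, self.cov_matrix, size=n, method="svd"
        )
        return PosteriorDraws.from_mu_C_delta(draws[:, 0], draws[:, 1])


def conjugate_posterior(
    data: SubgroupEstimates,
    prior_muC: NormalPrior,
    prior_delta: NormalPrior,
) -> GaussianPosterior:
    """Exact posterior for independent untruncated normal priors.

    The likelihood mean of (mu_hat_B, mu_hat_C) is re-expressed through
    mu_B = mu_C + delta, giving a linear-Gaussian model in
    theta = (mu_C, delta); the posterior is bivariate normal.  A prior sd
    of zero is treated as a point mass (the parameter stays fixed at its
    prior mean).  Posterior variances are strictly smaller than prior
    variances whenever the data are informative.
    """
    for p in (prior_muC, prior_delta):
        if p.truncation_upper is not None:
            raise ValueError("conjugate path requires untruncated priors")
    y = data.y
    Sigma = data.cov_matrix
    free_c, free_d = prior_muC.sd > 0, prior_delta.sd > 0
    if free_c and free_d:
        X = np.array([[1.0, 1.0], [1.0, 0.0]])
        m0 = np.array([prior_muC.mean, prior_delta.mean])
        V0 = np.diag([prior_muC.variance, prior_delta.variance])
        m, V = _gaussian_update(y, Sigma, X, np.zeros(2), m0, V0)
        return GaussianPosterior((m[0], m[1]), ((V[0, 0], V[0, 1]),
                                                (V[1, 0], V[1, 1])))
    if free_c:  # delta fixed at its prior mean
        a = prior_delta.mean
        X = np.array([[1.0], [1.0]])
        m, V = _gaussian_update(
            y, Sigma, X, np.array([a, 0.0]),
            np.array([prior_muC.mean]), np.array([[prior_muC.variance]]),
        )
        return GaussianPosterior((m[0], a), ((V[0, 0], 0.0), (0.0, 0.0)))
    if free_d:  # mu_C fixed at its prior mean
        c = prior_muC.mean
        X = np.array([[1.0], [0.0]])
        m, V = _gaussian_update(
            y, Sigma, X, np.array([c, c]),
            np.array([prior_delta.mean]), np.array([[prior_delta.variance]]),
        )
        return GaussianPosterior((c, m[0]), ((0.0, 0.0), (0.0, V[0, 0])))
    return GaussianPosterior((prior_muC.mean, prior_delta.mean),
                             ((0.0, 0.0), (0.0, 0.0)))


def conjugate_posterior_bivariate(
    data: SubgroupEstimates, prior: BivariateNormalPrior
) -> GaussianPosterior:
    """Exact posterior for a joint normal prior on (mu_B, mu_C).

    The identity design makes this a standard multivariate normal-normal
    update; the result is re-expressed in the (mu_C, delta)
    parameterization for a uniform interface.
    """
    m, V = _gaussian_update(
        data.y, data.cov_matrix, np.eye(2), np.zeros(2),
        prior.mean_vector, prior.cov_matrix,
    )
    # (mu_B, mu_C) -> (mu_C, delta) with delta = mu_B - mu_C
    A = np.array([[0.0, 1.0], [1.0, -1.0]])
    mt = A @ m
    Vt = A @ V @ A.T
    return GaussianPosterior((mt[0], mt[1]), ((Vt[0, 0], Vt[0, 1]),
                                              (Vt[1, 0], Vt[1, 1])))


# ---------------------------------------------------------------------------
# Gibbs / Metropolis samplers


def _truncnorm_upper(mean: float, sd: float, upper: Optional[float],
                     rng: np.random.Generator) -> float:
    """One draw from N(mean, sd^2) truncated to (-inf, upper]."""
    if upper is None:
        return mean + sd * rng.standard_normal()
    cap = ndtr((upper - mean) / sd)
    u = rng.uniform(0.0, cap)
    # guard against u == 0 at extreme truncation
    u = max(u, 1e-300)
    return mean + sd * ndtri(u)


class _Likelihood:
    """Precomputed precision pieces of the bivariate normal likelihood."""

    def __init__(self, data: SubgroupEstimates):
        Lam = np.linalg.inv(data.cov_matrix)
        self.l11 = Lam[0, 0]
        self.l12 = Lam[0, 1]
        self.l22 = Lam[1, 1]
        self.yB = data.mu_hat_B
        self.yC = data.mu_hat_C
        # s1 = u' Lam v, s2 with u = (1,1) (mu_C direction), v = (1,0) (delta)
        self.s1 = self.l11 + self.l12
        self.s2 = self.l12 + self.l22
        self.uLu = self.l11 + 2.0 * self.l12 + self.l22
        self.uLy = self.s1 * self.yB + self.s2 * self.yC
        self.vLy = self.l11 * self.yB + self.l12 * self.yC

    def loglik(self, mu_B: float, mu_C: float) -> float:
        rB = self.yB - mu_B
        rC = self.yC - mu_C
        return -0.5 * (self.l11 * rB * rB + 2.0 * self.l12 * rB * rC
                       + self.l22 * rC * rC)

    def cond_mu_C(self, delta: float, prior: NormalPrior):
        """Mean/sd of mu_C given delta under a normal prior on mu_C."""
        prec = self.uLu
        lin = self.uLy - delta * self.s1
        if prior.sd > 0:
            prec += 1.0 / prior.variance
            lin += prior.mean / prior.variance
        return lin / prec, 1.0 / math.sqrt(prec)

    def cond_delta(self, mu_C: float, mean0: float, var0: float):
        """Mean/sd of delta given mu_C under a N(mean0, var0) prior."""
        prec = self.l11 + 1.0 / var0
        lin = self.vLy - mu_C * self.s1 + mean0 / var0
        return lin / prec, 1.0 / math.sqrt(prec)


def _chain_normal(data, spec, n_iter, burn, thin, rng):
    lik = _Likelihood(data)
    pc: NormalPrior = spec.mu_C
    pd: NormalPrior = spec.delta
    mu_C = data.mu_hat_C if pc.sd > 0 else pc.mean
    if pc.truncation_upper is not None:
        mu_C = min(mu_C, pc.truncation_upper)
    delta = (data.mu_hat_B - data.mu_hat_C) if pd.sd > 0 else pd.mean
    if pd.truncation_upper is not None:
        delta = min(delta, pd.truncation_upper)
    # overdispersed start
    mu_C += 0.1 * rng.standard_normal() * (pc.sd > 0)
    if pc.truncation_upper is not None:
        mu_C = min(mu_C, pc.truncation_upper)
    keep_c, keep_d = [], []
    for i in range(n_iter):
        if pd.sd > 0:
            m, s = lik.cond_delta(mu_C, pd.mean, pd.variance)
            delta = _truncnorm_upper(m, s, pd.truncation_upper, rng)
        if pc.sd > 0:
            m, s = lik.cond_mu_C(delta, pc)
            mu_C = _truncnorm_upper(m, s, pc.truncation_upper, rng)
        if i >= burn and (i - burn) % thin == 0:
            keep_c.append(mu_C)
            keep_d.append(delta)
    return {"mu_C": np.array(keep_c), "delta": np.array(keep_d)}


def _chain_discrete(data, spec, n_iter, burn, thin, rng):
    lik = _Likelihood(data)
    pc: NormalPrior = spec.mu_C
    dp: DiscretePrior = spec.delta
    values = np.asarray(dp.values)
    logp = np.log(np.maximum(np.asarray(dp.probs), 1e-300))
    mu_C = data.mu_hat_C if pc.sd > 0 else pc.mean
    m_idx = int(np.argmin(np.abs(values - (data.mu_hat_B - data.mu_hat_C))))
    keep_c, keep_d, keep_m = [], [], []
    for i in range(n_iter):
        # M | mu_C : categorical, log-weights = log p_j + loglik(delta = d_j)
        rB = lik.yB - (mu_C + values)
        rC = lik.yC - mu_C
        logw = logp - 0.5 * (lik.l11 * rB * rB + 2.0 * lik.l12 * rB * rC
                             + lik.l22 * rC * rC)
        g = rng.gumbel(size=logw.size)
        m_idx = int(np.argmax(logw + g))
        delta = float(values[m_idx])
        if pc.sd > 0:
            m, s = lik.cond_mu_C(delta, pc)
            mu_C = _truncnorm_upper(m, s, pc.truncation_upper, rng)
        if i >= burn and (i - burn) % thin == 0:
            keep_c.append(mu_C)
            keep_d.append(delta)
            keep_m.append(m_idx)
    return {"mu_C": np.array(keep_c), "delta": np.array(keep_d),
            "M": np.array(keep_m)}


def _logmarg_y_given_muC(data: SubgroupEstimates, mu_C: float, s2: float) -> float:
    """log N(y; (mu_C, mu_C), Sigma + s2 * e_B e_B')  (delta integrated out)."""
    vB = data.var_B + s2
    vC = data.var_C
    cov = data.cov_BC
    det = vB * vC - cov * cov
    rB = data.mu_hat_B - mu_C
    rC = data.mu_hat_C - mu_C
    quad = (vC * rB * rB - 2.0 * cov * rB * rC + vB * rC * rC) / det
    return -0.5 * (math.log(det) + quad)


def _chain_spike_slab(data, spec, n_iter, burn, thin, rng):
    lik = _Likelihood(data)
    pc: NormalPrior = spec.mu_C
    sp: SpikeSlabPrior = spec.delta
    s2 = {0: sp.spike_sd**2, 1: sp.slab_sd**2}
    mu_C = data.mu_hat_C if pc.sd > 0 else pc.mean
    delta = data.mu_hat_B - data.mu_hat_C
    R, P = 1, 0.5
    keep = {"mu_C": [], "delta": [], "R": [], "P": []}
    for i in range(n_iter):
        # R | mu_C, P : collapsed over delta
        l1 = _logmarg_y_given_muC(data, mu_C, s2[1])
        l0 = _logmarg_y_given_muC(data, mu_C, s2[0])
        logit = math.log(P) - math.log1p(-P) + l1 - l0
        w = 1.0 / (1.0 + math.exp(-logit))
        R = 1 if rng.uniform() < w else 0
        # delta | R, mu_C : conjugate normal
        m, s = lik.cond_delta(mu_C, 0.0, s2[R])
        delta = m + s * rng.standard_normal()
        # P | R ~ Beta(1 + R, 2 - R)
        P = float(rng.beta(1.0 + R, 2.0 - R))
        P = min(max(P, 1e-12), 1.0 - 1e-12)
        if pc.sd > 0:
            m, s = lik.cond_mu_C(delta, pc)
            mu_C = _truncnorm_upper(m, s, pc.truncation_upper, rng)
        if i >= burn and (i - burn) % thin == 0:
            keep["mu_C"].append(mu_C)
            keep["delta"].append(delta)
            keep["R"].append(R)
            keep["P"].append(P)
    return {k: np.array(v) for k, v in keep.items()}


def _chain_bivariate(data, prior, n_iter, burn, thin, rng):
    post = conjugate_posterior_bivariate(data, prior)
    # Gibbs on the exact (mu_C, delta) posterior via its normal conditionals
    m = post.mean_vector
    V = post.cov_matrix
    cond_sd_c = math.sqrt(max(V[0, 0] - V[0, 1] ** 2 / V[1, 1], 1e-300))
    cond_sd_d = math.sqrt(max(V[1, 1] - V[0, 1] ** 2 / V[0, 0], 1e-300))
    mu_C, delta = data.mu_hat_C, data.mu_hat_B - data.mu_hat_C
    keep_c, keep_d = [], []
    for i in range(n_iter):
        mc = m[0] + V[0, 1] / V[1, 1] * (delta - m[1])
        mu_C = mc + cond_sd_c * rng.standard_normal()
        md = m[1] + V[0, 1] / V[0, 0] * (mu_C - m[0])
        delta = md + cond_sd_d * rng.standard_normal()
        if i >= burn and (i - burn) % thin == 0:
            keep_c.append(mu_C)
            keep_d.append(delta)
    return {"mu_C": np.array(keep_c), "delta": np.array(keep_d)}


def _chain_grid(data, grid, n_iter, burn, thin, rng):
    # The posterior over the grid cells is categorical with constant
    # weights, so the "chain" draws are independent.
    lik = _Likelihood(data)
    muB = np.asarray(grid.muB_values)
    muC = np.asarray(grid.muC_values)
    P = np.asarray(grid.joint_probs)
    logw = np.full(P.shape, -np.inf)
    for i in range(muC.size):
        for j in range(muB.size):
            if P[i, j] > 0:
                logw[i, j] = math.log(P[i, j]) + lik.loglik(muB[j], muC[i])
    w = np.exp(logw - logw.max()).ravel()
    w /= w.sum()
    n_keep = (n_iter - burn + thin - 1) // thin
    cells = rng.choice(w.size, size=n_keep, p=w)
    ii, jj = np.unravel_index(cells, P.shape)
    return {"mu_C": muC[ii], "mu_B_direct": muB[jj]}


def _chain_rectified(data, prior: RectifiedJointPrior, n_iter, burn, thin, rng,
                     prop_sd=(0.25, 0.35)):
    lik = _Likelihood(data)
    a, b, c, d, e = prior.a, prior.b, prior.c, prior.d, prior.e

    def logpost(yC: float, yB: float) -> float:
        mu_C = min(0.0, yC)
        mu_B = min(0.0, yB)
        v = d * d + e * mu_C
        if v <= 0.0:
            return -math.inf
        lp = -0.5 * ((yC - a) / b) ** 2
        lp += -0.5 * (yB - c * mu_C) ** 2 / v - 0.5 * math.log(v)
        return lp + lik.loglik(mu_B, mu_C)

    yC = min(data.mu_hat_C, -1e-3) + 0.05 * rng.standard_normal()
    yB = min(data.mu_hat_B, -1e-3) + 0.05 * rng.standard_normal()
    lp = logpost(yC, yB)
    keep_c, keep_b = [], []
    n_acc = 0
    for i in range(n_iter):
        yC_new = yC + prop_sd[0] * rng.standard_normal()
        lp_new = logpost(yC_new, yB)
        if math.log(rng.uniform()) < lp_new - lp:
            yC, lp = yC_new, lp_new
            n_acc += 1
        yB_new = yB + prop_sd[1] * rng.standard_normal()
        lp_new = logpost(yC, yB_new)
        if math.log(rng.uniform()) < lp_new - lp:
            yB, lp = yB_new, lp_new
        if i >= burn and (i - burn) % thin == 0:
            keep_c.append(min(0.0, yC))
            keep_b.append(min(0.0, yB))
    return {"mu_C": np.array(keep_c), "mu_B_direct": np.array(keep_b),
            "_accept_rate": np.full(len(keep_c), n_acc / n_iter)}


def _split_rhat_ess(arr: np.ndarray) -> tuple[float, float]:
    import arviz as az

    if np.allclose(arr, arr.ravel()[0]):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr)), float(az.ess(arr))


def mcmc_posterior(
    data: SubgroupEstimates,
    spec: JointPriorSpec,
    settings: McmcSettings,
) -> PosteriorDraws:
    """Sample the joint posterior of (mu_B, mu_C, delta) under any prior.

    Dispatches to the family-specific sampler, pools nothing across chains
    (arrays stay chain-shaped), and attaches split-Rhat and bulk effective
    sample size per parameter in ``diagnostics``.  Reproducible given the
    seed in ``settings``.
    """
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    if spec.parameterization == "muC_delta":
        if isinstance(spec.delta, NormalPrior):
            chain_fn = lambda rng: _chain_normal(
                data, spec, settings.iterations_per_chain,
                settings.burn_in, settings.thin, rng)
        elif isinstance(spec.delta, DiscretePrior):
            chain_fn = lambda rng: _chain_discrete(
                data, spec, settings.iterations_per_chain,
                settings.burn_in, settings.thin, rng)
        elif isinstance(spec.delta, SpikeSlabPrior):
            chain_fn = lambda rng: _chain_spike_slab(
                data, spec, settings.iterations_per_chain,
                settings.burn_in, settings.thin, rng)
        else:  # pragma: no cover
            raise TypeError(f"unsupported delta prior {type(spec.delta)}")
    else:
        joint = spec.joint
        if isinstance(joint, BivariateNormalPrior):
            chain_fn = lambda rng: _chain_bivariate(
                data, joint, settings.iterations_per_chain,
                settings.burn_in, settings.thin, rng)
        elif isinstance(joint, RectifiedJointPrior):
            chain_fn = lambda rng: _chain_rectified(
                data, joint, settings.iterations_per_chain,
                settings.burn_in, settings.thin, rng)
        elif hasattr(joint, "joint_probs"):
            chain_fn = lambda rng: _chain_grid(
                data, joint, settings.iterations_per_chain,
                settings.burn_in, settings.thin, rng)
        else:  # pragma: no cover
            raise TypeError(f"unsupported joint prior {type(joint)}")

    chains = [chain_fn(np.random.default_rng(s)) for s in seeds]
    mu_C = np.stack([ch["mu_C"] for ch in chains])
    if "mu_B_direct" in chains[0]:
        mu_B = np.stack([ch["mu_B_direct"] for ch in chains])
    else:
        mu_B = mu_C + np.stack([ch["delta"] for ch in chains])
    aux = {}
    for name in ("M", "R", "P"):
        if name in chains[0]:
            aux[name] = np.stack([ch[name] for ch in chains])
    draws = PosteriorDraws(mu_B=mu_B, mu_C=mu_C, delta=mu_B - mu_C, aux=aux)

    diagnostics: dict[str, float] = {}
    bad = []
    for name in ("mu_B", "mu_C", "delta"):
        rhat, ess = _split_rhat_ess(getattr(draws, name))
        diagnostics[f"rhat_{name}"] = rhat
        diagnostics[f"ess_{name}"] = ess
        if not math.isnan(rhat) and rhat > 1.01:
            bad.append((name, rhat))
    if "_accept_rate" in chains[0]:
        diagnostics["accept_rate"] = float(chains[0]["_accept_rate"][0])
    draws.diagnostics = diagnostics
    if bad:
        warnings.warn(
            "possible non-convergence, split-Rhat above 1.01: "
            + ", ".join(f"{n}={r:.3f}" for n, r in bad),
            stacklevel=2,
        )
    return draws


# ---------------------------------------------------------------------------
# summaries and derived quantities


def summarize_samples(x: np.ndarray) -> ParamSummary:
    """Mean / sd / equal-tailed 95% interval / P(< 0) of one draw array."""
    x = np.asarray(x, dtype=float).ravel()
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    lo, hi = (float(q) for q in np.quantile(x, [0.025, 0.975]))
    flagged = not (lo <= mean <= hi)
    return ParamSummary(mean=mean, sd=sd, ci_lo=lo, ci_hi=hi,
                        prob_below_0=float(np.mean(x < 0)), flagged=flagged)


def summarize(draws: PosteriorDraws, min_draws: int = 1000) -> PosteriorSummary:
    """Posterior summaries of mu_B, mu_C, delta and auxiliary variables."""
    if draws.n_total < min_draws:
        raise ValueError(
            f"need at least {min_draws} retained draws, got {draws.n_total}"
        )
    params = {name: summarize_samples(draws.flat(name))
              for name in ("mu_B", "mu_C", "delta")}
    if "P" in draws.aux:
        params["P"] = summarize_samples(draws.flat("P"))
    aux_probs = {}
    for name in ("M", "R"):
        if name in draws.aux:
            vals = draws.flat(name).astype(int)
            counts = np.bincount(vals)
            aux_probs[name] = {int(k): float(c / vals.size)
                               for k, c in enumerate(counts) if c > 0}
    return PosteriorSummary(params=params, aux_probs=aux_probs)


def overall_effect(draws: PosteriorDraws, spec: OverallEffectSpec) -> np.ndarray:
    """Per-draw overall effect mu_A = pi * mu_B + (1 - pi) * mu_C.

    A weighted-average approximation to the all-comer effect; exact for
    collapsible effect measures, approximate for hazard ratios.
    """
    return spec.pi * draws.mu_B + (1.0 - spec.pi) * draws.mu_C


class SignProbs(NamedTuple):
    p_mu_B_below_0: float
    p_mu_C_below_0: float
    p_delta_below_0: float


def sign_probabilities(draws: PosteriorDraws) -> SignProbs:
    """Monte-Carlo posterior probabilities that each parameter is negative."""
    return SignProbs(
        float(np.mean(draws.mu_B < 0)),
        float(np.mean(draws.mu_C < 0)),
        float(np.mean(draws.delta < 0)),
    )
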