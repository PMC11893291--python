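"""Turning elicited probability grids into continuous joint priors.

Expert beliefs about the two subgroup effects are elicited as a discrete
joint probability table over a small set of candidate (mu_B, mu_C) values
(hazard ratios 0.5, 0.6, ..., 1.0 on the log scale in the worked example):
a marginal distribution for mu_C and, for each candidate mu_C, a
conditional distribution for mu_B, multiplied into a joint grid.  Since
underlying beliefs are continuous, the grid is then converted into a
continuous joint prior in one of two ways:

* moment matching -- a bivariate normal with exactly the mean vector and
  covariance matrix implied by the grid;
* least-squares fitting of a right-rectified-normal joint family, which
  additionally encodes that harm (positive effects) is implausible and
  that "no effect" carries a point mass.  The plane is partitioned into
  rectangular regions (the Cartesian product of interval sets on each
  axis), the model-implied probability of each region is computed, and the
  five constants (a, b, c, d, e) are chosen to minimize the sum of squared
  differences from the grid's observed region probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .priors import BivariateNormalPrior, RectifiedJointPrior, rectified_cdf

__all__ = [
    "ElicitationGrid",
    "RegionPartition",
    "RectifiedFitResult",
    "build_grid_from_marginal_and_conditionals",
    "moment_match_bivariate",
    "rectified_region_probabilities",
    "fit_rectified_prior",
]


@dataclass
class ElicitationGrid:
    """Discrete joint probability table over (mu_B, mu_C) values.

    ``joint_probs[i, j]`` is the probability that mu_C equals
    ``muC_values[i]`` and mu_B equals ``muB_values[j]``.  Probabilities are
    renormalized with a warning if they miss 1 by more than 1e-6.
    """

    muB_values: np.ndarray
    muC_values: np.ndarray
    joint_probs: np.ndarray

    def __post_init__(self) -> None:
        self.muB_values = np.asarray(self.muB_values, dtype=float)
        self.muC_values = np.asarray(self.muC_values, dtype=float)
        self.joint_probs = np.asarray(self.joint_probs, dtype=float)
        if self.joint_probs.shape != (self.muC_values.size, self.muB_values.size):
            raise ValueError("joint_probs shape must be (len muC, len muB)")
        for v in (self.muB_values, self.muC_values):
            if np.any(np.diff(v) <= 0):
                raise ValueError("grid values must be strictly increasing")
        if np.any(self.joint_probs < 0):
            raise ValueError("probabilities must be non-negative")
        total = float(self.joint_probs.sum())
        if abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"grid probabilities sum to {total:.6g}; renormalizing",
                stacklevel=2,
            )
            self.joint_probs = self.joint_probs / total

    @property
    def marginal_muC(self) -> np.ndarray:
        return self.joint_probs.sum(axis=1)

    @property
    def marginal_muB(self) -> np.ndarray:
        return self.joint_probs.sum(axis=0)

    def log_joint_mass(self, mu_B: float, mu_C: float) -> float:
        jb = np.flatnonzero(self.muB_values == mu_B)
        ic = np.flatnonzero(self.muC_values == mu_C)
        if jb.size == 0 or ic.size == 0:
            return -math.inf
        p = self.joint_probs[ic[0], jb[0]]
        return math.log(p) if p > 0 else -math.inf

    def sample_joint(self, n: int, rng: np.random.Generator):
        flat = self.joint_probs.ravel()
        cells = rng.choice(flat.size, size=n, p=flat / flat.sum())
        ii, jj = np.unravel_index(cells, self.joint_probs.shape)
        return self.muB_values[jj], self.muC_values[ii]

    # -- CSV round trip: row index = HR values for subgroup C, columns = B

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.joint_probs,
            index=np.exp(self.muC_values),
            columns=np.exp(self.muB_values),
        )
        df.index.name = "hr_C"
        df.to_csv(path, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "ElicitationGrid":
        df = pd.read_csv(path, index_col=0)
        return cls(
            muB_values=np.log(df.columns.to_numpy(dtype=float)),
            muC_values=np.log(df.index.to_numpy(dtype=float)),
            joint_probs=df.to_numpy(dtype=float),
        )


def build_grid_from_marginal_and_conditionals(
    muB_values: Sequence[float],
    muC_values: Sequence[float],
    marginal_muC: Sequence[float],
    conditional_muB_given_muC: np.ndarray,
) -> ElicitationGrid:
    """Joint grid as P(mu_C = v_i) * P(mu_B = w_j | mu_C = v_i).

    ``conditional_muB_given_muC`` has one row per mu_C value; each row must
    sum to 1 (within 1e-6), as must the marginal.
    """
    marginal = np.asarray(marginal_muC, dtype=float)
    cond = np.asarray(conditional_muB_given_muC, dtype=float)
    if abs(marginal.sum() - 1.0) > 1e-6:
        raise ValueError("marginal probabilities must sum to 1")
    if np.any(np.abs(cond.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each conditional row must sum to 1")
    return ElicitationGrid(
        muB_values=np.asarray(muB_values, dtype=float),
        muC_values=np.asarray(muC_values, dtype=float),
        joint_probs=marginal[:, None] * cond,
    )


def moment_match_bivariate(grid: ElicitationGrid) -> BivariateNormalPrior:
    """Bivariate normal with exactly the grid's first two moments."""
    P = grid.joint_probs
    pB = grid.marginal_muB
    pC = grid.marginal_muC
    mB = float(pB @ grid.muB_values)
    mC = float(pC @ grid.muC_values)
    vB = float(pB @ (grid.muB_values - mB) ** 2)
    vC = float(pC @ (grid.muC_values - mC) ** 2)
    cBC = float(
        ((grid.muC_values - mC)[:, None] * (grid.muB_values - mB)[None, :] * P).sum()
    )
    if vB <= 0 or vC <= 0 or vB * vC - cBC**2 <= 0:
        raise ValueError("degenerate grid: implied covariance not positive definite")
    return BivariateNormalPrior(mean=(mB, mC), cov=((vB, cBC), (cBC, vC)))


@dataclass(frozen=True)
class RegionPartition:
    """Intervals on the real line splitting the plane into rectangles.

    ``breakpoints`` b_1 < ... < b_K define K + 1 half-open intervals
    (-inf, b_1], (b_1, b_2], ..., (b_K, inf).  The same set is used on both
    axes, giving (K + 1)^2 rectangular regions.
    """

    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "breakpoints", tuple(float(b) for b in self.breakpoints)
        )
        if len(self.breakpoints) < 1:
            raise ValueError("need at least one breakpoint")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def from_hr_breakpoints(cls, hrs=(0.55, 0.65, 0.75, 0.85, 0.95)):
        """Default partition at hazard ratios 0.55, 0.65, ..., 0.95."""
        return cls(tuple(math.log(h) for h in hrs))

    @property
    def n_intervals(self) -> int:
        return len(self.breakpoints) + 1

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate(([-np.inf], self.breakpoints, [np.inf]))

    def interval_index(self, x: float) -> int:
        """Index of the half-open interval (edge_k, edge_{k+1}] holding x."""
        return int(np.searchsorted(np.asarray(self.breakpoints), x, side="left"))

    def interval_probs_rectified(self, mu: float, sd: float) -> np.ndarray:
        """P(Z in each interval) for Z ~ right-rectified N(mu, sd^2).

        The atom at zero falls in whichever interval contains 0.
        """
        edges = self.edges
        cdf = np.array([rectified_cdf(x, mu, sd) for x in edges])
        return np.diff(cdf)


@dataclass
class RectifiedFitResult:
    """Outcome of the least-squares fit of the rectified joint prior."""

    params: RectifiedJointPrior
    observed_probs: np.ndarray
    expected_probs: np.ndarray
    sse: float
    n_starts: int
    n_converged: int
    start_objectives: np.ndarray = field(default_factory=lambda: np.array([]))


def _representative_muC(
    partition: RegionPartition, grid: ElicitationGrid, weighted: bool = True
) -> list[Optional[float]]:
    """Representative mu_C value per interval, taken from the grid.

    When several grid values fall in one interval they are averaged,
    weighted by their marginal probabilities if ``weighted`` (falling back
    to a plain average when those weights vanish).  Intervals holding no
    grid value get ``None`` (the caller substitutes the midpoint).
    """
    reps: list[Optional[float]] = []
    marg = grid.marginal_muC
    for k in range(partition.n_intervals):
        mask = np.array(
            [partition.interval_index(v) == k for v in grid.muC_values]
        )
        if not mask.any():
            reps.append(None)
            continue
        vals = grid.muC_values[mask]
        w = marg[mask] if weighted else np.ones(mask.sum())
        if w.sum() <= 0:
            w = np.ones(vals.size)
        reps.append(float(np.average(vals, weights=w)))
    return reps


def _finite_midpoints(partition: RegionPartition) -> np.ndarray:
    edges = partition.edges
    mids = np.empty(partition.n_intervals)
    for k in range(partition.n_intervals):
        lo, hi = edges[k], edges[k + 1]
        if math.isinf(lo):
            mids[k] = hi - 0.05
        elif math.isinf(hi):
            mids[k] = lo + 0.05
        else:
            mids[k] = 0.5 * (lo + hi)
    return mids


def rectified_region_probabilities(
    params: RectifiedJointPrior,
    partition: RegionPartition,
    grid: ElicitationGrid,
    weighted_representatives: bool = True,
) -> np.ndarray:
    """Model-implied probabilities of the rectangular regions.

    Marginal interval probabilities for mu_C come from the rectified CDF;
    conditional interval probabilities for mu_B are evaluated at a
    representative mu_C value per interval (the grid's values falling in
    that interval, probability-weighted), approximating the integral over
    the interval.  Entry ``[k_C, k_B]`` is the product of the two factors.
    """
    K = partition.n_intervals
    marg = partition.interval_probs_rectified(params.a, params.b)
    reps = _representative_muC(partition, grid, weighted=weighted_representatives)
    mids = _finite_midpoints(partition)
    E = np.zeros((K, K))
    for k in range(K):
        rep = reps[k]
        if rep is None:
            rep = float(mids[k])
        mean = params.conditional_mean(rep)
        var = params.conditional_var(rep)
        if var == 0.0:
            cond = np.zeros(K)
            cond[partition.interval_index(min(0.0, mean))] = 1.0
        else:
            cond = partition.interval_probs_rectified(mean, math.sqrt(var))
        E[k, :] = marg[k] * cond
    return E


def observed_region_probabilities(
    partition: RegionPartition, grid: ElicitationGrid
) -> np.ndarray:
    """Aggregate the grid's cell masses into the partition's regions."""
    K = partition.n_intervals
    O = np.zeros((K, K))
    for i, vC in enumerate(grid.muC_values):
        kC = partition.interval_index(vC)
        for j, vB in enumerate(grid.muB_values):
            kB = partition.interval_index(vB)
            O[kC, kB] += grid.joint_probs[i, j]
    return O


def fit_rectified_prior(
    grid: ElicitationGrid,
    partition: Optional[RegionPartition] = None,
    starts: int = 20,
    seed: int = 0,
    weighted_representatives: bool = True,
) -> RectifiedFitResult:
    """Least-squares fit of the five rectified-prior constants.

    Minimizes sum_i (O_i - E_i)^2 over (a, b, c, d, e) with b, d kept
    positive (log-parameterized), using multistart Nelder-Mead from
    randomized perturbations of moment-based initial guesses.  The
    objective is non-smooth (atoms and the max() in the conditional
    variance), which is why a derivative-free simplex with restarts is
    used.  Deterministic given seed and start count.
    """
    if partition is None:
        partition = RegionPartition.from_hr_breakpoints()
    O = observed_region_probabilities(partition, grid)

    def unpack(x):
        a, log_b, c, log_d, e = x
        return RectifiedJointPrior(a, math.exp(log_b), c, math.exp(log_d), e)

    def objective(x):
        try:
            p = unpack(x)
        except (OverflowError, ValueError):
            return 1e6
        E = rectified_region_probabilities(
            p, partition, grid, weighted_representatives=weighted_representatives
        )
        return float(((O - E) ** 2).sum())

    # moment-based initial guess
    mm = moment_match_bivariate(grid)
    mB, mC = mm.mean
    vB, vC = mm.cov_matrix[0, 0], mm.cov_matrix[1, 1]
    cBC = mm.cov_matrix[0, 1]
    slope = cBC / vC
    resid_var = max(vB - cBC**2 / vC, 1e-4)
    x0 = np.array(
        [mC, 0.5 * math.log(vC), slope, 0.5 * math.log(resid_var), 0.0]
    )

    rng = np.random.default_rng(seed)
    best = None
    start_objs = []
    n_converged = 0
    for s in range(starts):
        if s == 0:
            xs = x0.copy()
        else:
            xs = x0 + rng.normal(0.0, [0.1, 0.3, 0.2, 0.3, 0.05])
        start_objs.append(objective(xs))
        res = optimize.minimize(
            objective, xs, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-12},
        )
        if res.success:
            n_converged += 1
        if best is None or res.fun < best.fun:
            best = res
    if n_converged == 0:
        raise RuntimeError(
            f"rectified-prior fit failed to converge in {starts} starts; "
            f"best objective {best.fun:.3g}"
        )
    params = unpack(best.x)
    E = rectified_region_probabilities(
        params, partition, grid, weighted_representatives=weighted_representatives
    )
    return RectifiedFitResult(
        params=params,
        observed_probs=O,
        expected_probs=E,
        sse=float(best.fun),
        n_starts=starts,
        n_converged=n_converged,
        start_objectives=np.asarray(start_objs),
    )
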