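"""Null distributions of support and confidence under independence.

For an association rule A -> B mined from n baskets, let the indicator of the
antecedent be Bernoulli(p1) and the indicator of the consequent Bernoulli(p2),
independent of each other.  The estimated support n_AB/n is then binomial with
success probability p12 = p1*p2, and its one-sided (1-alpha) upper bound

    s_min = p1*p2 + z_alpha * sqrt(p1*p2*(1 - p1*p2)/n)

is the *minimum support* a rule must strictly exceed to be called meaningful.

The estimated confidence is the ratio C = X/Z of two dependent binomials
(X = #A&B, Z = #A).  C has no closed-form quantile -- its variance does not
even exist, because E(1/Z) diverges -- so the *minimum confidence* is the
(1-alpha) upper quantile of the exact discrete null distribution

    P(C = c) = sum_z Bin(z, cz, p2) * Bin(n, z, p1),

conditioned on Z >= 1 (C is defective at Z = 0) and renormalised by
1 - (1-p1)^n.

Two reporting conventions for the discrete quantile are provided (see
``minimum_confidence``): a 0.001-grid convention used for reference tables of
critical values, and an exact achievable-ratio convention used for per-rule
thresholds during mining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, norm

__all__ = [
    "RuleCounts",
    "ItemProbabilities",
    "SupportConfidenceEstimate",
    "ThresholdPair",
    "ConfidenceDistribution",
    "estimate_item_probabilities",
    "z_quantile",
    "minimum_support",
    "confidence_distribution",
    "minimum_confidence",
    "critical_value_table",
    "back_solve_joint_probability",
]

# atom enumeration is O(n^2) in memory; beyond this the grid path must be used
_MAX_EXACT_N = 4000

_CDF_TOL = 1e-12


@dataclass(frozen=True)
class RuleCounts:
    """Raw tallies behind a rule: basket total and marginal/joint counts."""

    n: int
    n_A: int
    n_B: int
    n_AB: int

    def __post_init__(self) -> None:
        for name in ("n", "n_A", "n_B", "n_AB"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_AB > min(self.n_A, self.n_B):
            raise ValueError("n_AB cannot exceed min(n_A, n_B)")
        if max(self.n_A, self.n_B) > self.n:
            raise ValueError("marginal counts cannot exceed n")


@dataclass(frozen=True)
class ItemProbabilities:
    """Marginal, joint and conditional probabilities estimated from counts.

    ``p2_given_1`` is None when the antecedent never occurs (n_A = 0).
    """

    p1: float
    p2: float
    p12: float
    p2_given_1: float | None


@dataclass(frozen=True)
class SupportConfidenceEstimate:
    """Estimated support n_AB/n and confidence n_AB/n_A (None when n_A = 0)."""

    support: float
    confidence: float | None

    @classmethod
    def from_counts(cls, counts: RuleCounts) -> "SupportConfidenceEstimate":
        conf = counts.n_AB / counts.n_A if counts.n_A > 0 else None
        return cls(support=counts.n_AB / counts.n, confidence=conf)


@dataclass(frozen=True)
class ThresholdPair:
    """Dynamic thresholds for one rule at one significance level."""

    s_min: float
    c_min: float
    alpha: float
    z_alpha: float


def estimate_item_probabilities(counts: RuleCounts) -> ItemProbabilities:
    """Estimate p1 = n_A/n, p2 = n_B/n, p12 = n_AB/n and P(B|A)."""
    n = counts.n
    p2_given_1 = counts.n_AB / counts.n_A if counts.n_A > 0 else None
    return ItemProbabilities(
        p1=counts.n_A / n,
        p2=counts.n_B / n,
        p12=counts.n_AB / n,
        p2_given_1=p2_given_1,
    )


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 0.5):
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")


def z_quantile(alpha: float, *, rounded: bool = False) -> float:
    """One-sided upper standard-normal quantile z_alpha.

    With ``rounded=True`` the quantile is rounded to 3 decimals (1.645 at
    alpha = 0.05), the tabled value conventionally used in worked examples;
    the full-precision quantile is the default.
    """
    _check_alpha(alpha)
    z = float(norm.isf(alpha))
    return round(z, 3) if rounded else z


def minimum_support(
    p1: float,
    p2: float,
    n: int,
    alpha: float,
    *,
    rounded_z: bool = False,
    exact_binomial: bool = False,
) -> float:
    """Minimum support: one-sided (1-alpha) upper bound of n_AB/n under independence.

    Parameters
    ----------
    p1, p2
        Antecedent and consequent marginal probabilities (estimated as
        n_A/n and n_B/n).
    n
        Number of baskets/samples.
    alpha
        One-sided significance level in (0, 0.5].
    rounded_z
        Use the 3-decimal tabled normal quantile (compatibility with printed
        worked examples) instead of the full-precision quantile.
    exact_binomial
        Use the exact upper quantile of Bin(n, p1*p2)/n instead of the
        normal approximation.  The normal approximation is the default.
    """
    _check_alpha(alpha)
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("p1 and p2 must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    p = p1 * p2
    if p == 0.0 or p == 1.0:
        # degenerate joint probability: the variance term vanishes
        return p
    if exact_binomial:
        return float(binom.isf(alpha, n, p)) / n
    z = z_quantile(alpha, rounded=rounded_z)
    return min(1.0, p + z * math.sqrt(p * (1.0 - p) / n))


# ---------------------------------------------------------------------------
# exact confidence distribution


def _atom_arrays(n: int, p1: float, p2: float):
    """All (x, z) pairs with 1 <= z <= n, 0 <= x <= z, and their null mass.

    Mass of (x, z) is Bin(n, z, p1) * Bin(z, x, p2), renormalised by
    1 - (1-p1)^n so that the distribution conditions on Z >= 1.
    """
    z = np.arange(1, n + 1)
    w = binom.pmf(z, n, p1)
    norm_const = 1.0 - (1.0 - p1) ** n
    w = w / norm_const
    zz = np.repeat(z, z + 1)
    xx = np.concatenate([np.arange(zi + 1) for zi in z])
    mass = binom.pmf(xx, zz, p2) * np.repeat(w, z + 1)
    return xx, zz, mass


@dataclass
class ConfidenceDistribution:
    """Exact null PMF of the confidence ratio C = X/Z, conditional on Z >= 1.

    ``values`` are the distinct achievable ratios x/z in strictly increasing
    order; ``pmf`` the corresponding masses (summing to 1).
    """

    n: int
    p1: float
    p2: float
    values: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cdf = np.cumsum(self.pmf)

    def quantile(self, q: float) -> float:
        """Smallest achievable value v with P(C <= v) >= q."""
        i = int(np.searchsorted(self.cdf, q - _CDF_TOL))
        return float(self.values[min(i, len(self.values) - 1)])


def confidence_distribution(n: int, p1: float, p2: float) -> ConfidenceDistribution:
    """Build the exact null distribution of C = X/Z by atom enumeration.

    Equal ratios (e.g. 1/3 and 333/999) are merged by exact rational
    comparison of the gcd-reduced pairs, never by float equality.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < p1 <= 1.0):
        raise ValueError("p1 must be in (0, 1]: at p1 = 0 the antecedent count "
                         "Z is 0 almost surely and the ratio is degenerate")
    if not (0.0 <= p2 <= 1.0):
        raise ValueError("p2 must lie in [0, 1]")
    if n > _MAX_EXACT_N:
        raise ValueError(
            f"atom enumeration is quadratic in n; n = {n} exceeds {_MAX_EXACT_N}. "
            "Use minimum_confidence(..., convention='grid') for large n."
        )
    xx, zz, mass = _atom_arrays(n, p1, p2)
    keep = mass > 0.0  # p2 in {0, 1} puts zero mass on interior ratios
    xx, zz, mass = xx[keep], zz[keep], mass[keep]
    g = np.gcd(xx, zz)
    num = xx // g
    den = zz // g
    key = num * np.int64(n + 1) + den  # injective for den <= n
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    uniq_start = np.flatnonzero(np.r_[True, key_s[1:] != key_s[:-1]])
    pmf = np.add.reduceat(mass[order], uniq_start)
    uk = key_s[uniq_start]
    values = (uk // (n + 1)) / (uk % (n + 1))
    vorder = np.argsort(values)
    return ConfidenceDistribution(
        n=n, p1=p1, p2=p2, values=values[vorder], pmf=pmf[vorder]
    )


# ---------------------------------------------------------------------------
# minimum confidence


def _grid_cdf_at(n: int, p1: float, p2: float, k: int, grid_den: int,
                 z_lo: int, z_hi: int, w: np.ndarray) -> float:
    """P(round(C * grid_den) <= k) = P(C < (2k+1)/(2*grid_den)), half-up rounding.

    Exact integer arithmetic: x/z < (2k+1)/(2*grid_den)  <=>
    x <= ((2k+1)*z - 1) // (2*grid_den).
    """
    z = np.arange(z_lo, z_hi + 1, dtype=np.int64)
    x_max = ((2 * k + 1) * z - 1) // (2 * grid_den)
    return float(np.sum(w * binom.cdf(x_max, z, p2)))


def _minimum_confidence_grid(n: int, p1: float, p2: float, alpha: float,
                             grid_step: float) -> float:
    """Grid-midpoint critical value, binary search on the rounded-atom CDF.

    Achievable ratios are rounded half-up to the nearest multiple of
    ``grid_step``; the critical value is the midpoint between the last grid
    value whose CDF is below 1-alpha and the first at or above it.
    """
    grid_den = round(1.0 / grid_step)
    if not math.isclose(grid_den * grid_step, 1.0, rel_tol=1e-9):
        raise ValueError("grid_step must divide 1 (e.g. 0.001)")
    # truncate the Z-range to where Bin(n, p1) carries mass
    z_lo = max(1, int(binom.ppf(1e-15, n, p1)))
    z_hi = int(binom.isf(1e-15, n, p1))
    z = np.arange(z_lo, z_hi + 1, dtype=np.int64)
    log_tail = n * math.log1p(-p1) if p1 < 1.0 else -math.inf
    norm_const = -math.expm1(log_tail)  # 1 - (1-p1)^n, stable for large n
    w = binom.pmf(z, n, p1) / norm_const
    target = 1.0 - alpha - _CDF_TOL
    lo, hi = 0, grid_den  # F(grid_den) = 1 always
    while lo < hi:
        mid = (lo + hi) // 2
        if _grid_cdf_at(n, p1, p2, mid, grid_den, z_lo, z_hi, w) >= target:
            hi = mid
        else:
            lo = mid + 1
    return max(0.0, (lo - 0.5) * grid_step)


def _minimum_confidence_exact(n: int, p1: float, p2: float, alpha: float) -> float:
    """Achievable-ratio critical value.

    Let u be the smallest achievable ratio with P(C <= u) >= 1-alpha; the
    critical value is the midpoint between u and the next achievable ratio,
    so that strictly exceeding it is exactly the event {C > u}, which has
    null probability <= alpha.
    """
    dist = confidence_distribution(n, p1, p2)
    i = int(np.searchsorted(dist.cdf, 1.0 - alpha - _CDF_TOL))
    i = min(i, len(dist.values) - 1)
    if i == len(dist.values) - 1:
        return float(dist.values[i])
    return float(0.5 * (dist.values[i] + dist.values[i + 1]))


def minimum_confidence(
    n: int,
    p1: float,
    p2: float,
    alpha: float,
    *,
    convention: str = "grid",
    grid_step: float = 1e-3,
) -> float:
    """Minimum confidence: (1-alpha) upper quantile of the null ratio X/Z.

    Parameters
    ----------
    convention
        ``"grid"`` (default): achievable ratios are binned half-up to a grid
        of step ``grid_step`` and the critical value is the midpoint between
        the last grid value below the (1-alpha) quantile and the first at or
        above it.  This is the convention reference tables of critical values
        are printed in (every entry ends half-way between grid points).
        ``"exact"``: the midpoint between the smallest achievable ratio u
        with CDF(u) >= 1-alpha and the next achievable ratio -- the sharpest
        threshold such that exceeding it has null probability <= alpha.  Used
        for per-rule thresholds during mining (requires n <= 4000).
    """
    _check_alpha(alpha)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < p1 <= 1.0):
        raise ValueError("p1 must be in (0, 1]: at p1 = 0 the confidence "
                         "ratio is degenerate (Z = 0 almost surely)")
    if not (0.0 <= p2 <= 1.0):
        raise ValueError("p2 must lie in [0, 1]")
    if p2 == 0.0:
        return 0.0  # X = 0 a.s.: single atom at 0
    if p2 == 1.0:
        return 1.0  # X = Z a.s.: single atom at 1
    if convention == "grid":
        return _minimum_confidence_grid(n, p1, p2, alpha, grid_step)
    if convention == "exact":
        return _minimum_confidence_exact(n, p1, p2, alpha)
    raise ValueError(f"unknown convention {convention!r}; use 'grid' or 'exact'")


def critical_value_table(
    n: int,
    p1_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
    p2_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
    levels=(0.80, 0.90, 0.95, 0.99),
    *,
    grid_step: float = 1e-3,
):
    """Table of minimum confidences: p2 blocks x level rows x p1 columns.

    Returns a pandas DataFrame with a (p2, level) MultiIndex on the rows and
    p1 on the columns, matching the layout of printed critical-value tables.
    """
    import pandas as pd

    p1_grid = list(p1_grid)
    p2_grid = list(p2_grid)
    levels = list(levels)
    if not (p1_grid and p2_grid and levels):
        raise ValueError("grids and levels must be nonempty")
    rows = []
    index = []
    for p2 in p2_grid:
        for level in levels:
            alpha = 1.0 - level
            rows.append(
                [
                    minimum_confidence(n, p1, p2, alpha,
                                       convention="grid", grid_step=grid_step)
                    for p1 in p1_grid
                ]
            )
            index.append((p2, level))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["p2", "level"]),
        columns=pd.Index(p1_grid, name="p1"),
    )


# ---------------------------------------------------------------------------
# back-solving the screening quadratic


def back_solve_joint_probability(
    n: int, s: float, alpha: float, *, rounded_z: bool = False
) -> float:
    """Joint-probability root p* of the minimum-support equation at support s.

    Solves (n + z^2) p^2 - (2 n s + z^2) p + n s^2 = 0 for p = p1*p2 and
    returns the smaller root, the one with p <= s (the larger root is an
    artefact of squaring).  Plugging p* back into the minimum-support formula
    recovers s.  Screening use: for a rule observed at support s, consequents
    with p2 < p*/p1 keep the expected null support so far below s that
    reaching s has probability < alpha; a pre-specified support floor can
    therefore skip them before counting.
    """
    _check_alpha(alpha)
    if not (0.0 < s < 1.0):
        raise ValueError("s must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = z_quantile(alpha, rounded=rounded_z)
    if z == 0.0:  # alpha = 0.5: the quadratic collapses to n (p - s)^2 = 0
        return s
    z2 = z * z
    a = n + z2
    b = 2.0 * n * s + z2
    c = n * s * s
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        raise ValueError(
            f"support {s} is unattainable at n = {n}, alpha = {alpha}: "
            "the screening quadratic has no real root"
        )
    # smaller root, in the numerically stable form
    p_star = (b - math.sqrt(disc)) / (2.0 * a)
    return p_star
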