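"""Nonparametric battery for ordinal trend analysis.

Implements the tests used to relate synergy / overlap metrics to ordered
toxicity severity (Minor -> Moderate -> Major):

* D'Agostino-Pearson omnibus normality screen (justifies nonparametrics),
* Kruskal-Wallis with the rank eta-squared effect size eta2 = H/(N-1),
* Dunn's post-hoc z tests with Bonferroni correction and Cliff's delta,
* Jonckheere-Terpstra ordered-trend test (tie-corrected normal approximation
  or permutation null) with effect size r = Z/sqrt(N),
* Pearson/Spearman/OLS correlation suite.

All routines operate on plain numeric arrays; grouping into ordered severity
classes is the caller's responsibility (see :class:`OrderedGroups`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .datatypes import TrendResult

__all__ = [
    "OrderedGroups",
    "normality_test",
    "kruskal_wallis",
    "dunn_posthoc",
    "cliffs_delta",
    "jonckheere_terpstra",
    "correlation_suite",
]


@dataclass
class OrderedGroups:
    """Numeric samples in a fixed, explicit order (e.g. Minor, Moderate, Major)."""

    groups: list[np.ndarray]
    labels: list[str]

    def __init__(self, groups: Sequence[Iterable[float]], labels: Sequence[str] | None = None):
        self.groups = [np.asarray(list(g), dtype=float) for g in groups]
        if labels is None:
            labels = [f"group{i}" for i in range(len(self.groups))]
        if len(labels) != len(self.groups):
            raise ValueError("labels must align with groups")
        self.labels = list(labels)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    @property
    def n_total(self) -> int:
        return sum(self.sizes)

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.groups) if self.groups else np.array([])

    def reversed(self) -> "OrderedGroups":
        return OrderedGroups(list(reversed(self.groups)), list(reversed(self.labels)))


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    """Sizes of tie groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def normality_test(x: Iterable[float]) -> TrendResult:
    """D'Agostino-Pearson omnibus test of normality.

    Combines skewness and kurtosis z-scores into K^2 ~ chi2(2) under the
    null of normality. Requires n >= 20 for the asymptotic moments to be
    trustworthy.
    """
    arr = np.asarray(list(x), dtype=float)
    n = len(arr)
    if n < 20:
        raise ValueError(f"normality test requires n >= 20, got n = {n}")
    if np.ptp(arr) == 0:
        raise ValueError("normality test undefined for zero-variance sample")
    k2, p = stats.normaltest(arr)
    return TrendResult(
        test_name="dagostino_pearson",
        statistic=float(k2),
        p_value=float(p),
        effect_size=float("nan"),
        effect_name="none",
        direction="two_sided",
        n_per_group=[n],
    )


def _midranks(g: OrderedGroups) -> tuple[list[np.ndarray], np.ndarray]:
    pooled = g.pooled()
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for size in g.sizes:
        out.append(ranks[start : start + size])
        start += size
    return out, pooled


def kruskal_wallis(g: OrderedGroups) -> TrendResult:
    """Tie-corrected Kruskal-Wallis H with effect size eta2 = H/(N-1).

    The eta2 definition is the plain H/(N-1) variant (proportion of rank
    variance explained by group membership), not the (H-k+1)/(N-k)
    adjustment; see ``effect_variant`` in the pipeline config.
    """
    if g.k < 2:
        raise ValueError("Kruskal-Wallis requires >= 2 groups")
    if any(s == 0 for s in g.sizes):
        raise ValueError("all groups must be nonempty")
    n = g.n_total
    if n < 5:
        raise ValueError("Kruskal-Wallis requires total N >= 5")
    rank_groups, pooled = _midranks(g)
    if np.ptp(pooled) == 0:
        raise ValueError("Kruskal-Wallis undefined when all values are identical")
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (r.mean() - (n + 1) / 2.0) ** 2 for r in rank_groups
    )
    ties = _tie_counts(pooled)
    correction = 1.0 - float(np.sum(ties**3 - ties)) / (n**3 - n)
    h /= correction
    p = float(stats.chi2.sf(h, g.k - 1))
    return TrendResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        effect_size=float(h / (n - 1)),
        effect_name="eta_squared",
        direction="two_sided",
        n_per_group=g.sizes,
    )


def cliffs_delta(x: Iterable[float], y: Iterable[float]) -> float:
    """Cliff's delta in [-1, 1]: P(x > y) - P(x < y) over all cross pairs."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("Cliff's delta requires two nonempty samples")
    # rank-based O((n+m) log(n+m)) dominance count
    ys = np.sort(ya)
    gt = np.searchsorted(ys, xa, side="left").sum()  # y < x counts
    lt = (len(ys) - np.searchsorted(ys, xa, side="right")).sum()  # y > x
    return float((gt - lt) / (len(xa) * len(ya)))


def dunn_posthoc(
    g: OrderedGroups, correction: Literal["bonferroni"] = "bonferroni"
) -> list[TrendResult]:
    """Dunn's pairwise z tests on mean ranks, Bonferroni-corrected.

    Each pairwise result carries Cliff's delta (first group vs second) as the
    effect size; the Bonferroni family is the k(k-1)/2 group contrasts.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    # reuse KW guards
    kruskal_wallis(g)
    n = g.n_total
    rank_groups, pooled = _midranks(g)
    ties = _tie_counts(pooled)
    tie_term = float(np.sum(ties**3 - ties)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    n_pairs = g.k * (g.k - 1) // 2
    results = []
    for i, j in itertools.combinations(range(g.k), 2):
        ni, nj = g.sizes[i], g.sizes[j]
        se = math.sqrt(base_var * (1.0 / ni + 1.0 / nj))
        z = (rank_groups[i].mean() - rank_groups[j].mean()) / se
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))) * n_pairs)
        results.append(
            TrendResult(
                test_name="dunn",
                statistic=float(z),
                p_value=p,
                effect_size=cliffs_delta(g.groups[i], g.groups[j]),
                effect_name="cliffs_delta",
                direction="two_sided",
                n_per_group=[ni, nj],
                notes=f"{g.labels[i]} vs {g.labels[j]}; bonferroni x{n_pairs}",
            )
        )
    return results


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """J = sum over ordered pairs i<j of Mann-Whitney counts with half ties."""
    j_stat = 0.0
    for i in range(len(groups)):
        xs = np.sort(groups[i])
        for jdx in range(i + 1, len(groups)):
            y = groups[jdx]
            lt = np.searchsorted(xs, y, side="left").sum()
            ties = (np.searchsorted(xs, y, side="right") - np.searchsorted(xs, y, side="left")).sum()
            j_stat += float(lt) + 0.5 * float(ties)
    return j_stat


def _jt_moments(g: OrderedGroups) -> tuple[float, float]:
    """Tie-corrected null mean and variance of J."""
    n = g.n_total
    sizes = np.asarray(g.sizes, dtype=float)
    ties = _tie_counts(g.pooled()).astype(float)
    mean = (n**2 - np.sum(sizes**2)) / 4.0
    t1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
        - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 72.0
    t2 = (
        np.sum(sizes * (sizes - 1) * (sizes - 2))
        * np.sum(ties * (ties - 1) * (ties - 2))
        / (36.0 * n * (n - 1) * (n - 2))
    )
    t3 = (
        np.sum(sizes * (sizes - 1))
        * np.sum(ties * (ties - 1))
        / (8.0 * n * (n - 1))
    )
    return float(mean), float(t1 + t2 + t3)


def _enumerate_assignments(pooled: np.ndarray, sizes: list[int]):
    """Yield every distinct assignment of pooled indices into ordered groups."""
    idx = tuple(range(len(pooled)))

    def rec(remaining: tuple, size_idx: int, acc: list):
        if size_idx == len(sizes) - 1:
            yield acc + [remaining]
            return
        for combo in itertools.combinations(remaining, sizes[size_idx]):
            rest = tuple(i for i in remaining if i not in set(combo))
            yield from rec(rest, size_idx + 1, acc + [combo])

    for assignment in rec(idx, 0, []):
        yield [pooled[list(part)] for part in assignment]


def _n_assignments(sizes: list[int]) -> int:
    total = sum(sizes)
    count = 1
    for s in sizes:
        count *= math.comb(total, s)
        total -= s
    return count


def jonckheere_terpstra(
    g: OrderedGroups,
    alternative: Literal["increasing", "decreasing"] = "increasing",
    mode: Literal["normal_approx", "permutation"] = "normal_approx",
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> TrendResult:
    """Jonckheere-Terpstra test for a monotone location trend across ordered groups.

    ``normal_approx`` uses the tie-corrected null moments of J with a 0.5
    continuity correction on the tail probability (J is discrete; without the
    correction the approximate p drifts from the exact permutation p by more
    than 0.02 at small group sizes). ``permutation`` shuffles values across
    the fixed group sizes (exhaustively when the number of distinct
    assignments is <= ``n_perm``, otherwise Monte-Carlo with ``n_perm``
    draws). Z is signed so positive means an increasing trend; the effect
    size is r = Z/sqrt(N) from the uncorrected Z.
    """
    if g.k < 2:
        raise ValueError("Jonckheere-Terpstra requires >= 2 ordered groups")
    if any(s == 0 for s in g.sizes):
        raise ValueError("all groups must be nonempty")
    pooled = g.pooled()
    if np.ptp(pooled) == 0:
        raise ValueError("Jonckheere-Terpstra undefined when all values are identical")
    j_obs = _jt_statistic(g.groups)
    mean, var = _jt_moments(g)
    z = (j_obs - mean) / math.sqrt(var)
    n = g.n_total

    sd = math.sqrt(var)
    if mode == "normal_approx":
        # continuity-corrected tail probabilities of the discrete J
        if alternative == "increasing":
            p = float(stats.norm.sf((j_obs - 0.5 - mean) / sd))
        elif alternative == "decreasing":
            p = float(stats.norm.cdf((j_obs + 0.5 - mean) / sd))
        else:
            raise ValueError(f"unknown alternative: {alternative}")
    elif mode == "permutation":
        def extreme(j_val: float) -> bool:
            return j_val >= j_obs if alternative == "increasing" else j_val <= j_obs

        if _n_assignments(g.sizes) <= n_perm:
            hits = total = 0
            for groups in _enumerate_assignments(pooled, g.sizes):
                total += 1
                if extreme(_jt_statistic(groups)):
                    hits += 1
            p = hits / total
        else:
            gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            hits = 0
            bounds = np.cumsum(g.sizes)[:-1]
            for _ in range(n_perm):
                perm = gen.permutation(pooled)
                if extreme(_jt_statistic(np.split(perm, bounds))):
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown mode: {mode}")

    return TrendResult(
        test_name="jonckheere_terpstra",
        statistic=j_obs,
        p_value=p,
        effect_size=float(z / math.sqrt(n)),
        effect_name="r",
        direction=alternative,
        n_per_group=g.sizes,
        notes=f"Z={z:.6g}; mode={mode}",
    )


def correlation_suite(x: Iterable[float], y: Iterable[float]) -> dict[str, float]:
    """Pearson r, Spearman rho, and the OLS best-fit line with R^2.

    For simple linear regression R^2 = r^2; slope/intercept allow scatter
    reconstruction.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must be paired")
    if len(xa) < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    pear = stats.pearsonr(xa, ya)
    spear = stats.spearmanr(xa, ya)
    lin = stats.linregress(xa, ya)
    return {
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
        "r_squared": float(lin.rvalue**2),
        "slope": float(lin.slope),
        "intercept": float(lin.intercept),
    }
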