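"""Statistical primitives shared by every pipeline stage.

Centralizing the tests here keeps sidedness, tie handling and degenerate-input
conventions identical across stages.  All tests are two-sided; the direction
of an effect is carried separately in :class:`TestResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_formats import GeneSet


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    direction: str  # '+', '-', '0'
    method: str
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not math.isnan(self.p_value)


def _direction(delta: float, tol: float = 0.0) -> str:
    if delta > tol:
        return "+"
    if delta < -tol:
        return "-"
    return "0"


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties and the t-approximation p value.

    Missing values are dropped pairwise-complete.  A ranked vector with zero
    variance leaves rho undefined: (nan, nan) is returned, never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, restored to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------


def welch_t_from_stats(m1, v1, n1, m2, v2, n2):
    """Welch t statistic, df and two-sided p from sufficient statistics.

    Vectorized over leading dimensions; groups with zero variance in both
    arms and equal means get p = 1 by convention.
    """
    m1, v1, m2, v2 = (np.asarray(a, dtype=float) for a in (m1, v1, m2, v2))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2 * sps.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    return t, df, p


def two_sample_test(a, b, method: str = "welch_t") -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    delta = float(np.mean(a) - np.mean(b)) if a.size and b.size else float("nan")
    if method == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValueError("welch_t needs >= 2 observations per group")
        t, _, p = welch_t_from_stats(
            a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
        )
        flags = ["degenerate"] if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 else []
        return TestResult(float(t), float(p), (a.size, b.size), _direction(delta), "welch_t", flags)
    if method == "rank_sum":
        if a.size < 1 or b.size < 1:
            raise ValueError("rank_sum needs >= 1 observation per group")
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        # exact enumeration where cheap and exactness is well-defined
        exact = a.size <= 10 and b.size <= 10 and not has_ties
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        med_delta = float(np.median(a) - np.median(b))
        return TestResult(
            float(res.statistic), float(res.pvalue), (a.size, b.size),
            _direction(med_delta), "rank_sum",
        )
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# k-sample tests
# ---------------------------------------------------------------------------


def k_sample_test(groups, method: str = "anova") -> TestResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    ns = tuple(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(float("nan"), 1.0, ns, "0", method, ["degenerate"])
    if method == "anova":
        if sum(ns) - len(groups) < 1:
            raise ValueError("ANOVA needs residual degrees of freedom")
        stat, p = sps.f_oneway(*groups)
    elif method == "kruskal_wallis":
        stat, p = sps.kruskal(*groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    means = [g.mean() for g in groups]
    direction = _direction(means[int(np.argmax(means))] - means[int(np.argmin(means))])
    return TestResult(float(stat), float(p), ns, direction, method)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def ora_test(
    hits,
    pathway: GeneSet,
    universe,
    min_overlap: int = 3,
    alpha: float = 0.01,
) -> dict:
    """Hypergeometric upper-tail over-representation of ``hits`` in ``pathway``.

    Enrichment is reported only when the overlap is at least ``min_overlap``
    genes *and* p < ``alpha`` (both thresholds configurable).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hits_u = set(hits) & uni
    path_u = set(pathway.genes) & uni
    overlap = len(hits_u & path_u)
    M, K, n = len(universe), len(path_u), len(hits_u)
    p = float(sps.hypergeom.sf(overlap - 1, M, K, n))
    return {
        "pathway": pathway.name,
        "overlap": overlap,
        "pathway_size": K,
        "n_hits": n,
        "universe_size": M,
        "p_value": p,
        "enriched": bool(overlap >= min_overlap and p < alpha),
    }
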