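"""Single-sample gene-set variation scoring.

The scoring pipeline converts a genes x samples expression matrix into a
samples x signatures score matrix in three steps:

1. **Kernel CDF.** For each gene, a non-parametric estimate of its
   expression distribution across samples: with a Gaussian kernel the value
   of gene *i* in sample *j* is mapped to
   ``mean_k Phi((x_ij - x_ik) / h_i)`` with per-gene bandwidth
   ``h_i = SD_i * bandwidth_factor``; with ``kernel="none"`` the plain
   empirical CDF is used.  This expresses each value as its relative
   position in the gene's cross-sample distribution, making the score
   independent of per-gene scale.

2. **Symmetric rank statistic.** Within each sample, genes are ranked by
   decreasing CDF value (rank 1 = highest).  The statistic
   ``r = |p/2 - rank|`` up-weights genes at either expression extreme and
   gives mid-ranked genes weight near zero.

3. **Weighted random walk.** Walking down the ranked gene list of each
   sample, in-set genes add ``|r|^tau`` (normalized by the in-set total)
   and out-of-set genes subtract ``1/(p - k)``.  The score is the maximum
   positive deviation of the walk minus the magnitude of the maximum
   negative deviation; both deviations live in [0, 1] so the score is
   bounded in [-1, 1].

Scores are invariant under strictly increasing per-gene transformations of
the input because only the CDF ranks enter the walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_formats import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

_SD_EPS = 1e-8  # bandwidth floor for zero-variance genes


@dataclass(frozen=True)
class GsvaParams:
    kernel: str = "gaussian"  # "gaussian" | "none"
    bandwidth_factor: float = 0.25  # per-gene bandwidth = SD * factor
    tau: float = 1.0  # weight exponent on the rank statistic
    statistic: str = "max_diff"

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "none"):
            raise ValueError(f"kernel must be 'gaussian' or 'none', got {self.kernel!r}")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.statistic != "max_diff":
            raise ValueError(f"unsupported statistic {self.statistic!r}")


@dataclass
class ScoreTable:
    """Samples x signatures score matrix with the per-set overlap actually used."""

    sample_ids: list[str]
    signature_names: list[str]
    scores: np.ndarray  # samples x signatures
    overlap_sizes: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.signature_names)

    def column(self, name: str) -> pd.Series:
        return self.to_frame()[name]


def kernel_cdf(expr: ExpressionMatrix, params: GsvaParams = GsvaParams()) -> np.ndarray:
    """Per-gene kernel-smoothed empirical CDF evaluated at each sample's value."""
    x = expr.values
    p, n = x.shape
    if n < 2:
        raise ValueError(f"kernel CDF needs at least 2 samples, got {n}")
    if params.kernel == "none":
        # plain ECDF: fraction of samples with value <= x_ij
        return (x[:, :, None] >= x[:, None, :]).mean(axis=2)
    sd = x.std(axis=1, ddof=1)
    h = np.maximum(sd * params.bandwidth_factor, _SD_EPS)
    out = np.empty((p, n))
    # chunk genes so the (chunk, n, n) difference tensor stays small
    chunk = max(1, int(4e6 // (n * n)))
    for start in range(0, p, chunk):
        sl = slice(start, min(start + chunk, p))
        diff = (x[sl, :, None] - x[sl, None, :]) / h[sl, None, None]
        out[sl] = ndtr(diff).mean(axis=2)
    return out


def rank_statistic(cdf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample decreasing-CDF ranks (1 = highest; ties by input gene order)
    and the symmetric statistic ``|p/2 - rank|``."""
    p, n = cdf.shape
    order = np.argsort(-cdf, axis=0, kind="stable")  # walk order: gene index at position l
    ranks = np.empty((p, n), dtype=np.int64)
    pos = np.arange(1, p + 1)
    for j in range(n):
        ranks[order[:, j], j] = pos
    r = np.abs(p / 2.0 - ranks)
    return ranks, r


def _walk_orders(cdf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Walk order (gene index by position, per sample) and |r|^1 sorted by position."""
    order = np.argsort(-cdf, axis=0, kind="stable")
    p = cdf.shape[0]
    pos_stat = np.abs(p / 2.0 - np.arange(1, p + 1))  # r of the gene at position l
    return order, pos_stat


def enrichment_walk(
    order: np.ndarray,
    r_sorted: np.ndarray,
    set_mask: np.ndarray,
    tau: float = 1.0,
    statistic: str = "max_diff",
) -> np.ndarray:
    """Score every sample's ranked gene list against one gene set.

    Parameters
    ----------
    order : (p, n) int array; ``order[l, j]`` is the gene at walk position
        ``l`` of sample ``j`` (position 0 = rank 1).
    r_sorted : (p,) rank-statistic values by position (identical across
        samples because the statistic depends only on the rank).
    set_mask : (p,) boolean membership over gene indices.
    """
    if statistic != "max_diff":
        raise ValueError(f"unsupported statistic {statistic!r}")
    p, n = order.shape
    k = int(set_mask.sum())
    if k == 0:
        raise ValueError("gene set has no overlap with the expression matrix")
    if k == p:
        raise ValueError("gene set covers every gene in the matrix; score undefined")
    inset = set_mask[order]  # (p, n): is the gene at position l in the set?
    w = (np.abs(r_sorted) ** tau)[:, None] * inset
    denom = w.sum(axis=0)
    # all-zero in-set weight can only occur for tau -> inf pathologies; guard
    denom = np.where(denom == 0, 1.0, denom)
    pos = np.cumsum(w, axis=0) / denom
    neg = np.cumsum(~inset, axis=0) / (p - k)
    dev = pos - neg
    max_pos = np.maximum(dev, 0.0).max(axis=0)
    max_neg = np.maximum(-dev, 0.0).max(axis=0)
    return max_pos - max_neg


def score_matrix(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    params: GsvaParams = GsvaParams(),
) -> ScoreTable:
    """Score every sample against every gene set; the full pipeline."""
    cdf = kernel_cdf(expr, params)
    order, r_sorted = _walk_orders(cdf)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    p = expr.n_genes
    scores = np.empty((expr.n_samples, len(sets)))
    overlap_sizes: dict[str, int] = {}
    for c, gs in enumerate(sets):
        present = [gene_index[g] for g in gs.genes if g in gene_index]
        dropped = len(gs.genes) - len(present)
        if dropped:
            logger.warning(
                "signature %r: %d of %d genes absent from matrix", gs.name, dropped, len(gs.genes)
            )
        if not present:
            raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
        if len(present) == p:
            raise ValueError(f"gene set {gs.name!r} covers all matrix genes")
        mask = np.zeros(p, dtype=bool)
        mask[present] = True
        overlap_sizes[gs.name] = len(present)
        scores[:, c] = enrichment_walk(order, r_sorted, mask, params.tau, params.statistic)
    return ScoreTable(
        sample_ids=list(expr.sample_ids),
        signature_names=[gs.name for gs in sets],
        scores=scores,
        overlap_sizes=overlap_sizes,
    )


def score_per_group(
    expr: ExpressionMatrix,
    sets: list[GeneSet],
    groups: pd.Series,
    params: GsvaParams = GsvaParams(),
) -> ScoreTable:
    """Score each group of samples (e.g. cancer type) separately.

    The kernel CDF — hence the score — is estimated within each group, the
    default for per-cancer-type analyses; pooled scoring is ``score_matrix``.
    """
    groups = groups.reindex(expr.sample_ids)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])[:5]
        raise KeyError(f"samples without group label: {missing}")
    frames = []
    overlap: dict[str, int] = {}
    for _, members in groups.groupby(groups, sort=True):
        sub = expr.subset_samples(list(members.index))
        st = score_matrix(sub, sets, params)
        overlap = st.overlap_sizes
        frames.append(st.to_frame())
    combined = pd.concat(frames).reindex(expr.sample_ids)
    return ScoreTable(
        sample_ids=list(combined.index),
        signature_names=list(combined.columns),
        scores=combined.to_numpy(),
        overlap_sizes=overlap,
    )
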