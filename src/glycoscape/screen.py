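"""Transcriptome screening between glycolysis-high and -low tumors.

Differential signature enrichment (Welch t on per-sample enrichment scores),
differential expression (rank-sum on log2(TPM+1) with a 1.5-linear-fold +
BH-adjusted p < 0.05 conjunctive rule), cross-cancer recurrence, candidate
correlation ranking, and the hypoxia/gene quadrant stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GroupLabels
from .gsva import ScoreTable
from .io_formats import ExpressionMatrix
from .stats import bh_adjust, spearman, two_sample_test

logger = logging.getLogger(__name__)


def diff_signature_enrichment(
    scores: ScoreTable,
    labels: GroupLabels,
    cancer_type: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-signature Welch t of enrichment scores, high vs low group.

    BH adjustment runs across signatures within the cohort; a signature is
    "differentially enriched" iff adj_p < alpha.
    """
    df = scores.to_frame()
    hi = [s for s in labels.samples("high") if s in df.index]
    lo = [s for s in labels.samples("low") if s in df.index]
    if len(hi) < 2 or len(lo) < 2:
        logger.info("diff enrichment skipped: high n=%d, low n=%d", len(hi), len(lo))
        return pd.DataFrame(
            columns=["signature", "cancer_type", "delta", "p", "adj_p", "enriched"]
        )
    rows = []
    for sig in df.columns:
        res = two_sample_test(df.loc[hi, sig], df.loc[lo, sig], method="welch_t")
        rows.append({
            "signature": sig,
            "cancer_type": cancer_type,
            "delta": float(df.loc[hi, sig].mean() - df.loc[lo, sig].mean()),
            "p": res.p_value,
        })
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["adj_p"] < alpha
    return out


def de_genes(
    expr: ExpressionMatrix,
    labels: GroupLabels,
    cancer_type: str = "all",
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum DE scan between high and low groups on log2(TPM+1).

    Fold change is the ratio of mean linear TPM+1 values (pseudocount kept
    for stability at zero); direction 'up'/'down' requires the linear fold
    change to reach ``fc_threshold`` AND adj_p < alpha, conjunctively.
    """
    df = expr.to_frame()
    hi = [s for s in labels.samples("high") if s in df.columns]
    lo = [s for s in labels.samples("low") if s in df.columns]
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError(f"need >= 3 samples per group, got high={len(hi)}, low={len(lo)}")
    a = df[hi].to_numpy()
    b = df[lo].to_numpy()
    # linear fold change from mean TPM+1
    lin_a = (2.0**a).mean(axis=1)
    lin_b = (2.0**b).mean(axis=1)
    log2_fc = np.log2(lin_a / lin_b)
    # vectorized two-sided Mann-Whitney per gene
    res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.array([np.unique(np.concatenate([a[i], b[i]])).size == 1
                         for i in range(a.shape[0])])
    p = np.where(constant, 1.0, p)
    adj = bh_adjust(p)
    fold = 2.0 ** np.abs(log2_fc)
    direction = np.where(
        (fold >= fc_threshold) & (adj < alpha),
        np.where(log2_fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame({
        "gene_id": expr.gene_ids,
        "cancer_type": cancer_type,
        "log2_fold_change": log2_fc,
        "p": p,
        "adj_p": adj,
        "direction": direction,
    })


def recurrent_genes(de_by_cancer: dict[str, pd.DataFrame], k: int = 13) -> pd.DataFrame:
    """Genes called 'up' in at least k cancer types, sorted by count then name."""
    n_types = len(de_by_cancer)
    if k > n_types:
        raise ValueError(f"k={k} exceeds the {n_types} cancer types analyzed")
    counts: dict[str, int] = {}
    for df in de_by_cancer.values():
        for g in df.loc[df["direction"] == "up", "gene_id"]:
            counts[g] = counts.get(g, 0) + 1
    rows = [{"gene_id": g, "n_up": c} for g, c in counts.items() if c >= k]
    out = pd.DataFrame(rows, columns=["gene_id", "n_up"])
    return out.sort_values(["n_up", "gene_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def candidate_rank(
    expr_by_cancer: dict[str, ExpressionMatrix],
    scores: pd.Series,
    candidates: list[str],
) -> pd.DataFrame:
    """Rank candidate genes by median per-cancer Spearman rho with the score.

    Ties break by gene name; candidates absent from every matrix are listed
    with missing status.
    """
    rows = []
    for gene in candidates:
        rhos = []
        for ct, expr in sorted(expr_by_cancer.items()):
            if gene not in expr.gene_ids:
                continue
            g = expr.to_frame().loc[gene]
            pair = pd.DataFrame({"g": g, "s": scores.reindex(g.index)}).dropna()
            if len(pair) < 3:
                continue
            rho, _ = spearman(pair["g"], pair["s"])
            if np.isfinite(rho):
                rhos.append(rho)
        if rhos:
            rows.append({
                "gene_id": gene,
                "median_rho": float(np.median(rhos)),
                "min_rho": float(np.min(rhos)),
                "max_rho": float(np.max(rhos)),
                "n_cancer_types": len(rhos),
                "missing": False,
            })
        else:
            rows.append({
                "gene_id": gene, "median_rho": float("nan"), "min_rho": float("nan"),
                "max_rho": float("nan"), "n_cancer_types": 0, "missing": True,
            })
    df = pd.DataFrame(rows)
    present = df[~df["missing"]].sort_values(
        ["median_rho", "gene_id"], ascending=[False, True], kind="stable"
    )
    absent = df[df["missing"]].sort_values("gene_id")
    out = pd.concat([present, absent], ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class QuadrantLabels:
    labels: pd.Series  # sample -> 'H+G+', 'H+G-', 'H-G+', 'H-G-'
    gene: str


def _median_split(values: pd.Series) -> pd.Series:
    """Top-50% split; ties broken by (value, sample_id) lexicographic order."""
    order = sorted(values.index, key=lambda s: (values[s], str(s)))
    n = len(order)
    k = n - n // 2  # top half gets the extra sample when n is odd
    top = set(order[n - k:])
    return pd.Series([s in top for s in values.index], index=values.index)


def quadrant_stratify(
    hyp_scores: pd.Series,
    expr: ExpressionMatrix,
    gene: str,
    targets: dict[str, pd.Series] | None = None,
) -> tuple[QuadrantLabels, pd.DataFrame]:
    """Double median split: hypoxia score, then the gene within each H stratum.

    Returns quadrant labels and per-quadrant summaries (mean/median of each
    requested target variable) plus pairwise Welch t p values between
    quadrants on each target.
    """
    if gene not in expr.gene_ids:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    g = expr.to_frame().loc[gene]
    common = hyp_scores.dropna().index.intersection(g.index)
    if len(common) < 4:
        raise ValueError(f"need >= 4 samples, got {len(common)}")
    h = hyp_scores.reindex(common)
    g = g.reindex(common)
    h_top = _median_split(h)
    lab = pd.Series(index=common, dtype=object)
    for is_top, stratum in ((True, "H+"), (False, "H-")):
        members = common[h_top == is_top]
        if len(members) == 0:
            continue
        g_top = _median_split(g.reindex(members))
        lab[members] = [stratum + ("G+" if t else "G-") for t in g_top]
    quad = QuadrantLabels(labels=lab, gene=gene)
    rows = []
    targets = targets or {}
    for q in ("H+G+", "H+G-", "H-G+", "H-G-"):
        members = lab.index[lab == q]
        row = {"quadrant": q, "n": len(members)}
        for name, vals in targets.items():
            v = vals.reindex(members).dropna()
            row[f"{name}_mean"] = float(v.mean()) if len(v) else float("nan")
            row[f"{name}_median"] = float(v.median()) if len(v) else float("nan")
        rows.append(row)
    summary = pd.DataFrame(rows)
    return quad, summary


def quadrant_pairwise_tests(quad: QuadrantLabels, values: pd.Series) -> pd.DataFrame:
    """Pairwise Welch t between quadrants on one target variable."""
    quads = ("H+G+", "H+G-", "H-G+", "H-G-")
    rows = []
    for i, qa in enumerate(quads):
        for qb in quads[i + 1:]:
            va = values.reindex(quad.labels.index[quad.labels == qa]).dropna()
            vb = values.reindex(quad.labels.index[quad.labels == qb]).dropna()
            if len(va) < 2 or len(vb) < 2:
                continue
            res = two_sample_test(va, vb, method="welch_t")
            rows.append({"a": qa, "b": qb, "delta": float(va.mean() - vb.mean()),
                         "p": res.p_value})
    return pd.DataFrame(rows)
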