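"""Single-cell branch: QC, normalization, per-cell scoring, spatial contrasts.

QC thresholds follow the bulk pipeline's upstream conventions: cells with
fewer than 200 total counts, fewer than 200 or more than 6000 expressed
genes, or more than 10% mitochondrial counts (``MT-`` symbol prefix) are
removed.  Counts are normalized to log2(1 + CP10K) — scoring is rank-based
per gene, so any monotone variance-stabilization choice yields the same
scores.  Cells then flow through the same scoring engine as bulk samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gsva import GsvaParams, score_matrix
from .io_formats import CellMatrix, ExpressionMatrix, GeneSet
from .stats import k_sample_test, spearman

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    min_counts: int = 200
    min_genes: int = 200
    max_genes: int = 6000
    max_mito_fraction: float = 0.10
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def qc_filter(
    cells: CellMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[CellMatrix, pd.DataFrame]:
    """Remove cells violating any QC rule; report why each cell failed."""
    counts = cells.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(thresholds.mito_prefix) for g in cells.gene_ids])
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
    report = pd.DataFrame(
        {
            "cell_id": cells.cell_ids,
            "total_counts": total.astype(int),
            "n_genes": n_genes.astype(int),
            "mito_fraction": mito_frac,
            "fail_low_counts": total < thresholds.min_counts,
            "fail_low_genes": n_genes < thresholds.min_genes,
            "fail_high_genes": n_genes > thresholds.max_genes,
            "fail_mito": mito_frac > thresholds.max_mito_fraction,
        }
    ).set_index("cell_id", drop=False)
    report["passed"] = ~report[
        ["fail_low_counts", "fail_low_genes", "fail_high_genes", "fail_mito"]
    ].any(axis=1)
    keep = report["passed"].to_numpy()
    if not keep.any():
        tally = {
            rule: int(report[rule].sum())
            for rule in ("fail_low_counts", "fail_low_genes", "fail_high_genes", "fail_mito")
        }
        raise ValueError(f"no cells survive QC; removal tally: {tally}")
    kept_ids = [c for c, k in zip(cells.cell_ids, keep) if k]
    filtered = CellMatrix(
        gene_ids=list(cells.gene_ids),
        cell_ids=kept_ids,
        counts=cells.counts[:, np.where(keep)[0]],
        cell_meta=cells.cell_meta.loc[kept_ids],
    )
    logger.info("QC: %d of %d cells pass", len(kept_ids), cells.n_cells)
    return filtered, report


def normalize_cells(cells: CellMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """log2(1 + CP10K) normalization; cells become the 'samples' axis."""
    counts = cells.counts.astype(float).toarray()
    total = counts.sum(axis=0)
    if (total == 0).any():
        bad = [c for c, t in zip(cells.cell_ids, total) if t == 0]
        raise ValueError(f"zero-total cell(s): {bad[:5]}")
    norm = np.log2(1.0 + scale * counts / total)
    return ExpressionMatrix(list(cells.gene_ids), list(cells.cell_ids), norm)


@dataclass
class CellScoreTable:
    table: pd.DataFrame  # index cell_id; score columns + patient, region + top30 flags
    score_correlation: tuple[float, float] | None = None  # (rho, p) glycolysis vs hypoxia

    def scores(self, name: str) -> pd.Series:
        return self.table[name]


def _top30_flags(values: pd.Series, frac: float = 0.30) -> pd.Series:
    """Flag exactly floor(frac*n) cells; ties broken by (value, cell_id)."""
    k = int(np.floor(frac * len(values)))
    order = sorted(values.index, key=lambda c: (values[c], str(c)))
    top = set(order[len(order) - k:]) if k else set()
    return pd.Series([c in top for c in values.index], index=values.index)


def score_cells(
    norm: ExpressionMatrix,
    signatures: list[GeneSet],
    cell_meta: pd.DataFrame,
    overlay_genes: tuple[str, ...] = ("P4HA1", "HSPA8"),
    params: GsvaParams = GsvaParams(),
) -> CellScoreTable:
    """Per-cell signature scores plus top-30% overlay flags.

    The glycolysis–hypoxia Spearman correlation across cells is reported
    when both signatures are present.
    """
    st = score_matrix(norm, signatures, params)
    tab = st.to_frame()
    tab = tab.join(cell_meta.reindex(tab.index))
    for sig in st.signature_names:
        tab[f"top30_{sig}"] = _top30_flags(tab[sig])
    ef = norm.to_frame()
    for gene in overlay_genes:
        if gene in ef.index:
            tab[f"top30_{gene}"] = _top30_flags(ef.loc[gene])
        else:
            logger.warning("overlay gene %r absent from matrix", gene)
    corr = None
    gly = next((s for s in st.signature_names if s.startswith("glycolysis")), None)
    hyp = next((s for s in st.signature_names if s.startswith("hypoxia")), None)
    if gly and hyp:
        corr = spearman(tab[gly], tab[hyp])
    return CellScoreTable(table=tab, score_correlation=corr)


def _stars(p: float) -> str:
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return mark
    return "ns"


def region_compare(
    cell_scores: CellScoreTable,
    score_columns: tuple[str, ...] = ("glycolysis22", "hypoxia14"),
    min_cells: int = 2,
) -> pd.DataFrame:
    """Per-patient one-way ANOVA of each score across core/edge/middle regions."""
    tab = cell_scores.table
    rows = []
    for patient, sub in tab.groupby("patient_id", sort=True):
        region_groups = {
            r: sub.loc[sub["region"] == r]
            for r in ("core", "edge", "middle")
            if (sub["region"] == r).sum() >= min_cells
        }
        if len(region_groups) < 2:
            rows.append({"patient_id": patient, "status": "skipped: fewer than 2 regions"})
            logger.info("patient %s skipped: fewer than 2 regions with >= %d cells",
                        patient, min_cells)
            continue
        for col in score_columns:
            groups = [g[col].to_numpy() for g in region_groups.values()]
            res = k_sample_test(groups, method="anova")
            means = {f"mean_{r}": float(g[col].mean()) for r, g in region_groups.items()}
            rows.append({
                "patient_id": patient, "score": col, "F": res.statistic,
                "p": res.p_value, "stars": _stars(res.p_value), "status": "ok",
                **means,
            })
    return pd.DataFrame(rows)
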