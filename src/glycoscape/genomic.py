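"""Genomic associations of glycolysis activity: CNAs, SNVs, TMB, aneuploidy.

Per cancer type: each gene's copy-number direction is called from the
gain/loss sample ratio (>2 defines the direction), scores are compared
between altered and copy-number-neutral tumors (Welch t), and p values are
Benjamini–Hochberg adjusted within the cohort — never pooled across types.
The driver panorama ranks annotated drivers by the number of cancer types
in which the directional test reaches p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CNAMatrix
from .stats import bh_adjust, k_sample_test, spearman, two_sample_test, welch_t_from_stats

logger = logging.getLogger(__name__)


@dataclass
class GeneCNACall:
    gene_id: str
    n_gain: int
    n_loss: int
    n_neutral: int
    ratio: float  # gain/loss (or loss/gain for losses); nan when undefined
    call: str  # 'gain' | 'loss' | 'ambiguous'


def call_gain_loss(cna: CNAMatrix, sample_ids=None) -> list[GeneCNACall]:
    """Per-gene cohort-level gain/loss call from the >2 sample-count ratio.

    A zero denominator with a nonzero numerator counts as exceeding 2 (the
    limit of the rule); 0/0 is ambiguous with an undefined ratio.
    """
    calls_df = cna.to_frame()
    if sample_ids is not None:
        calls_df = calls_df[list(sample_ids)]
    arr = calls_df.to_numpy()
    out = []
    for i, gene in enumerate(calls_df.index):
        row = arr[i]
        ng = int((row == 1).sum())
        nl = int((row == -1).sum())
        nn = int((row == 0).sum())
        if ng == 0 and nl == 0:
            out.append(GeneCNACall(gene, ng, nl, nn, float("nan"), "ambiguous"))
            continue
        if nl == 0:
            out.append(GeneCNACall(gene, ng, nl, nn, float("inf"), "gain"))
            continue
        if ng == 0:
            out.append(GeneCNACall(gene, ng, nl, nn, float("inf"), "loss"))
            continue
        gl = ng / nl
        if gl > 2:
            out.append(GeneCNACall(gene, ng, nl, nn, gl, "gain"))
        elif 1 / gl > 2:
            out.append(GeneCNACall(gene, ng, nl, nn, 1 / gl, "loss"))
        else:
            out.append(GeneCNACall(gene, ng, nl, nn, gl, "ambiguous"))
    return out


def _masked_welch(scores: np.ndarray, alt_mask: np.ndarray, ref_mask: np.ndarray):
    """Vectorized Welch t of scores[alt] vs scores[ref] over many genes.

    ``alt_mask``/``ref_mask`` are (genes x samples) boolean arrays.
    """
    s = scores.astype(float)
    n1 = alt_mask.sum(axis=1)
    n2 = ref_mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = (alt_mask @ s) / n1
        m2 = (ref_mask @ s) / n2
        q1 = (alt_mask @ s**2) / n1 - m1**2
        q2 = (ref_mask @ s**2) / n2 - m2**2
        v1 = q1 * n1 / np.maximum(n1 - 1, 1)
        v2 = q2 * n2 / np.maximum(n2 - 1, 1)
    v1 = np.maximum(v1, 0.0)
    v2 = np.maximum(v2, 0.0)
    t, df, p = welch_t_from_stats(m1, v1, n1, m2, v2, n2)
    return m1 - m2, p, n1, n2


def _associate(
    scores: pd.Series,
    alt: pd.DataFrame,
    neutral: pd.DataFrame,
    cancer_type: str,
    comparison: str,
    min_altered: int,
) -> pd.DataFrame:
    common = scores.index.intersection(alt.columns)
    s = scores.reindex(common).to_numpy()
    a = alt[common].to_numpy(bool)
    r = neutral[common].to_numpy(bool)
    n1 = a.sum(axis=1)
    n2 = r.sum(axis=1)
    testable = (n1 >= max(min_altered, 2)) & (n2 >= 2)
    delta, p, _, _ = _masked_welch(s, a, r)
    df = pd.DataFrame(
        {
            "gene_id": alt.index,
            "cancer_type": cancer_type,
            "comparison": comparison,
            "delta_mean_score": delta,
            "p": p,
            "n_altered": n1,
            "n_reference": n2,
            "tested": testable,
        }
    )
    skipped = df[~df["tested"]]
    if len(skipped):
        logger.info(
            "%s/%s: %d gene(s) skipped (arm below threshold)",
            cancer_type, comparison, len(skipped),
        )
    tested = df[df["tested"]].copy()
    tested["adj_p"] = bh_adjust(tested["p"].to_numpy()) if len(tested) else []
    return tested.drop(columns="tested").reset_index(drop=True)


def cna_association(
    scores: pd.Series,
    cna: CNAMatrix,
    clinical: pd.DataFrame,
    min_altered: int = 5,
) -> pd.DataFrame:
    """Per-gene bidirectional CNA association scan, per cancer type.

    Gains and losses are each tested against copy-number-neutral samples;
    BH adjustment is applied within each cancer type across all tests run
    in that cohort.
    """
    calls = cna.to_frame()
    tumors = clinical[clinical["sample_type"] == "tumor"]
    records = []
    for ct, sub in tumors.groupby("cancer_type", sort=True):
        samp = [s for s in sub.index if s in calls.columns and s in scores.index]
        if len(samp) < 4:
            continue
        sub_calls = calls[samp]
        s = scores.reindex(samp)
        frames = []
        for comparison, code in (("gain_vs_neutral", 1), ("loss_vs_neutral", -1)):
            alt = sub_calls == code
            neu = sub_calls == 0
            frames.append(
                _associate(s, alt, neu, str(ct), comparison, min_altered)
            )
        ct_df = pd.concat(frames, ignore_index=True)
        if len(ct_df):
            # BH within the cohort across both comparisons jointly
            ct_df["adj_p"] = bh_adjust(ct_df["p"].to_numpy())
        records.append(ct_df)
    if not records:
        return pd.DataFrame(
            columns=["gene_id", "cancer_type", "comparison", "delta_mean_score",
                     "p", "n_altered", "n_reference", "adj_p"]
        )
    return pd.concat(records, ignore_index=True)


def snv_association(
    scores: pd.Series,
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    min_altered: int = 5,
) -> pd.DataFrame:
    """Mutated-vs-wildtype Welch t per gene per cancer type (nonsynonymous only).

    Mutation multiplicity collapses to presence/absence per sample.
    """
    nonsyn = mutations[mutations["nonsynonymous"]]
    tumors = clinical[clinical["sample_type"] == "tumor"]
    records = []
    for ct, sub in tumors.groupby("cancer_type", sort=True):
        samp = [s for s in sub.index if s in scores.index]
        if len(samp) < 4:
            continue
        muts = nonsyn[nonsyn["sample_id"].isin(samp)]
        if muts.empty:
            continue
        carrier = (
            muts.assign(flag=True)
            .pivot_table(index="gene_id", columns="sample_id", values="flag",
                         aggfunc="any", fill_value=False)
            .reindex(columns=samp, fill_value=False)
            .astype(bool)
        )
        wt = ~carrier
        s = scores.reindex(samp)
        ct_df = _associate(s, carrier, wt, str(ct), "mutated_vs_wildtype", min_altered)
        if len(ct_df):
            ct_df["adj_p"] = bh_adjust(ct_df["p"].to_numpy())
        records.append(ct_df)
    if not records:
        return pd.DataFrame(
            columns=["gene_id", "cancer_type", "comparison", "delta_mean_score",
                     "p", "n_altered", "n_reference", "adj_p"]
        )
    return pd.concat(records, ignore_index=True)


def driver_association(
    scores: pd.Series,
    cna: CNAMatrix,
    clinical: pd.DataFrame,
    driver_roles: pd.Series,
    min_altered: int = 5,
) -> pd.DataFrame:
    """Directional driver scan: gain for oncogenes, loss for suppressors."""
    bad = set(driver_roles.unique()) - {"oncogene", "suppressor"}
    if bad:
        raise ValueError(
            f"driver annotation must be 'oncogene' or 'suppressor'; got {sorted(bad)}"
        )
    full = cna_association(scores, cna, clinical, min_altered=min_altered)
    wanted = driver_roles.map({"oncogene": "gain_vs_neutral", "suppressor": "loss_vs_neutral"})
    keep = []
    for gene, comparison in wanted.items():
        sub = full[(full["gene_id"] == gene) & (full["comparison"] == comparison)]
        keep.append(sub)
    out = pd.concat(keep, ignore_index=True) if keep else full.iloc[0:0]
    return out


def driver_panorama(
    assoc: pd.DataFrame,
    driver_roles: pd.Series,
    alpha: float = 0.05,
    top_n: int = 50,
) -> pd.DataFrame:
    """Rank drivers by the number of cancer types with directional p < alpha.

    Ties broken by mean |delta| (descending), then gene name.  Drivers absent
    from the association table get count 0 and a flag.
    """
    rows = []
    for gene, role in driver_roles.items():
        comparison = "gain_vs_neutral" if role == "oncogene" else "loss_vs_neutral"
        sub = assoc[(assoc["gene_id"] == gene) & (assoc["comparison"] == comparison)]
        if sub.empty:
            rows.append({"gene_id": gene, "role": role, "n_significant": 0,
                         "mean_abs_delta": 0.0, "missing": True})
            continue
        sig = sub[sub["p"] < alpha]
        rows.append({
            "gene_id": gene,
            "role": role,
            "n_significant": int(len(sig)),
            "mean_abs_delta": float(sub["delta_mean_score"].abs().mean()),
            "missing": False,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["n_significant", "mean_abs_delta", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_n) if top_n else df


def tmb(mutations: pd.DataFrame) -> pd.Series:
    """Per-sample count of nonsynonymous mutations (raw count, not per Mb)."""
    nonsyn = mutations[mutations["nonsynonymous"]]
    return nonsyn.groupby("sample_id").size().rename("tmb")


def burden_and_ploidy(
    scores: pd.Series,
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    group_labels: dict[str, "object"] | None = None,
) -> pd.DataFrame:
    """Per-cancer TMB group test, aneuploidy Spearman and doubling k-sample test."""
    burden = tmb(mutations)
    tumors = clinical[clinical["sample_type"] == "tumor"]
    rows = []
    for ct, sub in tumors.groupby("cancer_type", sort=True):
        samp = [s for s in sub.index if s in scores.index]
        s = scores.reindex(samp)
        row: dict = {"cancer_type": str(ct)}
        # TMB: high vs low glycolysis groups (rank sum)
        if group_labels and str(ct) in group_labels:
            lab = group_labels[str(ct)].labels
            hi = burden.reindex(lab.index[lab == "high"]).fillna(0)
            lo = burden.reindex(lab.index[lab == "low"]).fillna(0)
            if hi.size >= 2 and lo.size >= 2:
                res = two_sample_test(hi, lo, method="rank_sum")
                row.update(tmb_p=res.p_value, tmb_direction=res.direction)
        # aneuploidy Spearman
        aneu = sub["aneuploidy_score"].reindex(samp)
        pair = pd.DataFrame({"s": s, "a": aneu}).dropna()
        if len(pair) >= 3:
            rho, p = spearman(pair["s"], pair["a"])
            row.update(aneuploidy_rho=rho, aneuploidy_p=p)
        else:
            row.update(aneuploidy_status="skipped: insufficient aneuploidy data")
        # genome doubling classes
        dbl = sub["genome_doublings"].reindex(samp)
        groups = [
            s[dbl == g].dropna().to_numpy()
            for g in (0, 1, 2)
            if (dbl == g).sum() >= 2
        ]
        if len(groups) >= 2:
            res = k_sample_test(groups, method="anova")
            row.update(doubling_p=res.p_value, doubling_stat=res.statistic)
        rows.append(row)
    return pd.DataFrame(rows)
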