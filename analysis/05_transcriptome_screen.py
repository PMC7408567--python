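#!/usr/bin/env python
"""Transcriptome contrasts between glycolysis-high and -low tumors.

Differential signature enrichment, per-cancer DE at the conjunctive
1.5-fold + adj p < 0.05 rule, cross-cancer recurrence, hypoxia-score
correlation (with the overlap-free 16-gene variant), candidate-gene
correlation ranking, and the hypoxia x P4HA1 quadrant split.
"""

from pathlib import Path

import pandas as pd

from glycoscape.cohort import classify_per_cancer
from glycoscape.gsva import ScoreTable
from glycoscape.io_formats import read_clinical, read_matrix
from glycoscape.screen import (
    candidate_rank,
    de_genes,
    diff_signature_enrichment,
    quadrant_stratify,
    recurrent_genes,
)
from glycoscape.stats import spearman

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    expr = read_matrix(ROOT / "bundle" / "expr.tsv", kind="expression")
    clin = read_clinical(ROOT / "bundle" / "clinical.tsv")
    scores = pd.read_csv(ROOT / "scores.tsv", sep="\t", index_col=0)
    gly, hyp = scores["glycolysis22"], scores["hypoxia14"]
    groups = classify_per_cancer(gly, clin)
    eligible = {ct: gl for ct, gl in groups.items() if gl.eligible}

    # signature-level contrast per cancer type
    st = ScoreTable(list(scores.index), list(scores.columns),
                    scores.to_numpy(), {})
    enr = pd.concat(
        [diff_signature_enrichment(st, gl, cancer_type=ct) for ct, gl in eligible.items()],
        ignore_index=True,
    )
    enr.to_csv(ROOT / "diff_enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    # score-score correlation per cancer type (22-gene and overlap-free 16-gene)
    corr_rows = []
    tumors = clin[clin["sample_type"] == "tumor"]
    for ct, sub in tumors.groupby("cancer_type"):
        rho, p = spearman(gly.reindex(sub.index), hyp.reindex(sub.index))
        rho16, _ = spearman(scores["glycolysis16"].reindex(sub.index),
                            hyp.reindex(sub.index))
        corr_rows.append({"cancer_type": ct, "rho": rho, "p": p,
                          "rho_overlap_free": rho16})
        print(f"{ct}: glycolysis-hypoxia rho = {rho:.2f} "
              f"(overlap-free {rho16:.2f})")
    pd.DataFrame(corr_rows).to_csv(ROOT / "hypoxia_correlation.tsv", sep="\t",
                                   index=False, float_format="%.6g")

    # per-cancer DE and recurrence (threshold scaled to the cohort count)
    de_by_ct = {}
    for ct, gl in eligible.items():
        sub = expr.subset_samples(list(gl.labels.index))
        de_by_ct[ct] = de_genes(sub, gl, cancer_type=ct)
    pd.concat(de_by_ct.values(), ignore_index=True).to_csv(
        ROOT / "de_genes.tsv", sep="\t", index=False, float_format="%.6g")
    k = max(1, len(de_by_ct) - 1)
    rec = recurrent_genes(de_by_ct, k=k)
    rec.to_csv(ROOT / "recurrent_up_genes.tsv", sep="\t", index=False)
    print(f"{len(rec)} genes up-regulated in >= {k} of {len(de_by_ct)} cancer types")

    # candidate ranking: recurrent genes + the planted regulator
    candidates = sorted(set(rec["gene_id"]) | {"HSPA8", "P4HA1"})
    expr_by_ct = {ct: expr.subset_samples(list(sub.index))
                  for ct, sub in tumors.groupby("cancer_type")}
    ranking = candidate_rank(expr_by_ct, gly, candidates)
    ranking.to_csv(ROOT / "candidate_ranking.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print("top candidates by median rho:")
    print(ranking.head(5).to_string(index=False))

    # quadrant stratification on hypoxia score x P4HA1 expression
    quad, summary = quadrant_stratify(
        hyp.reindex(tumors.index).dropna(), expr, "P4HA1",
        targets={"glycolysis_score": gly},
    )
    summary.to_csv(ROOT / "quadrant.tsv", sep="\t", index=False, float_format="%.6g")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
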