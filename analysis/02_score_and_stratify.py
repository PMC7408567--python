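#!/usr/bin/env python
"""Score every sample, split cohorts into glycolysis-high/low groups, and
test tumor-vs-normal and cross-cancer score differences.

Reads results/bundle/ (from 01) and writes scores.tsv, labels.tsv,
tumor_normal.tsv and a cross-cancer Kruskal-Wallis summary under results/.
"""

from pathlib import Path

import pandas as pd

from glycoscape.cohort import classify_per_cancer, tumor_normal_compare, stage_association
from glycoscape.gsva import score_matrix, score_per_group
from glycoscape.io_formats import read_clinical, read_matrix
from glycoscape.signatures import all_signatures
from glycoscape.stats import k_sample_test

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    expr = read_matrix(ROOT / "bundle" / "expr.tsv", kind="expression")
    clin = read_clinical(ROOT / "bundle" / "clinical.tsv")

    scores = score_per_group(expr, all_signatures(), clin["cancer_type"]).to_frame()
    scores.index.name = "sample_id"
    scores.to_csv(ROOT / "scores.tsv", sep="\t", float_format="%.10g")
    gly = scores["glycolysis22"]

    groups = classify_per_cancer(gly, clin)
    rows = [{"sample_id": s, "cancer_type": ct, "group": lab, "eligible": gl.eligible}
            for ct, gl in groups.items() for s, lab in gl.labels.items()]
    pd.DataFrame(rows).to_csv(ROOT / "labels.tsv", sep="\t", index=False)
    for ct, gl in groups.items():
        print(f"{ct}: {gl.n_high} high / {gl.n_low} low"
              f"{'' if gl.eligible else '  (ineligible)'}")

    tn = tumor_normal_compare(gly, clin)
    pd.DataFrame(
        [{"cancer_type": ct, "p": r.p_value, "direction": r.direction}
         for ct, r in tn.items()]
    ).to_csv(ROOT / "tumor_normal.tsv", sep="\t", index=False)
    n_up = sum(r.direction == "+" and r.p_value < 0.05 for r in tn.values())
    print(f"tumor > normal glycolysis score in {n_up}/{len(tn)} cancer types (rank sum)")

    # cross-cancer comparison uses pooled scoring (per-type scoring centers
    # each cohort and would erase between-cancer differences by construction)
    pooled = score_matrix(expr, all_signatures()).to_frame()["glycolysis22"]
    tumors = clin[clin["sample_type"] == "tumor"]
    by_type = [pooled.reindex(sub.index).dropna().to_numpy()
               for _, sub in tumors.groupby("cancer_type")]
    kw = k_sample_test(by_type, method="kruskal_wallis")
    print(f"cross-cancer score heterogeneity: KW H = {kw.statistic:.1f}, p = {kw.p_value:.3g}")

    stage = stage_association(gly, clin)
    pd.DataFrame(
        [{"cancer_type": ct, "p": r.p_value, "direction": r.direction}
         for ct, r in stage.items()]
    ).to_csv(ROOT / "stage_iv_vs_i.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
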