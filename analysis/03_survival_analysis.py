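#!/usr/bin/env python
"""Survival analyses of the glycolysis-high vs -low groups.

Kaplan-Meier + log-rank per eligible cancer type, then univariate and
multivariate Cox models (glycolysis group, hypoxia group, stage) pooled
across cancer types.  Writes survival.tsv and cox.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from glycoscape.cohort import (
    classify_per_cancer,
    cox_by_covariates,
    encode_stage,
    survival_by_group,
)
from glycoscape.io_formats import read_clinical

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clin = read_clinical(ROOT / "bundle" / "clinical.tsv")
    scores = pd.read_csv(ROOT / "scores.tsv", sep="\t", index_col=0)
    gly, hyp = scores["glycolysis22"], scores["hypoxia14"]

    rows = []
    groups = classify_per_cancer(gly, clin)
    for ct, gl in groups.items():
        if not gl.eligible:
            continue
        fit = survival_by_group(gl, clin)
        rows.append({"cancer_type": ct, "logrank_chi2": fit.logrank_chi2,
                     "logrank_p": fit.logrank_p, "status": fit.status})
        print(f"{ct}: log-rank chi2 = {fit.logrank_chi2:.2f}, p = {fit.logrank_p:.3g}")
    pd.DataFrame(rows).to_csv(ROOT / "survival.tsv", sep="\t", index=False)

    tumors = clin[clin["sample_type"] == "tumor"]
    cov_uni = pd.DataFrame({"glycolysis_score": gly.reindex(tumors.index)}).dropna()
    uni = cox_by_covariates(clin, cov_uni)
    cov_multi = pd.DataFrame(
        {
            "glycolysis_score": gly.reindex(tumors.index),
            "hypoxia_score": hyp.reindex(tumors.index),
            "stage": encode_stage(tumors["stage"]),
        }
    ).dropna()
    multi = cox_by_covariates(clin, cov_multi)
    out = pd.concat(
        [uni.to_frame().assign(model="univariate"),
         multi.to_frame().assign(model="multivariate")]
    )
    out.index.name = "covariate"
    out.to_csv(ROOT / "cox.tsv", sep="\t", float_format="%.6g")
    print("univariate glycolysis HR per score unit: "
          f"{uni.hr[0]:.2f} ({uni.ci_low[0]:.2f}-{uni.ci_high[0]:.2f}), p = {uni.p[0]:.3g}")
    print("multivariate (adjusted for hypoxia score and stage): "
          f"HR {multi.hr[0]:.2f}, p = {multi.p[0]:.3g}")


if __name__ == "__main__":
    main()
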