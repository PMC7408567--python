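#!/usr/bin/env python
"""Associate glycolysis scores with CNAs, SNVs, TMB, aneuploidy and doubling.

Per-gene bidirectional CNA scan and mutated-vs-wildtype scan with per-cohort
BH adjustment; directional driver panorama over the annotated drivers; TMB /
aneuploidy / genome-doubling summaries.  Writes assoc_cna.tsv, assoc_snv.tsv,
driver_panorama.tsv and burden_ploidy.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from glycoscape.cohort import classify_per_cancer
from glycoscape.genomic import (
    burden_and_ploidy,
    cna_association,
    driver_panorama,
    snv_association,
)
from glycoscape.io_formats import read_clinical, read_matrix, read_mutations

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clin = read_clinical(ROOT / "bundle" / "clinical.tsv")
    cna = read_matrix(ROOT / "bundle" / "cna.tsv", kind="cna")
    muts = read_mutations(ROOT / "bundle" / "mutations.tsv")
    gly = pd.read_csv(ROOT / "scores.tsv", sep="\t", index_col=0)["glycolysis22"]

    assoc = cna_association(gly, cna, clin)
    assoc.to_csv(ROOT / "assoc_cna.tsv", sep="\t", index=False, float_format="%.6g")
    sig = assoc[assoc["adj_p"] < 0.05]
    print(f"CNA scan: {len(sig)} significant gene/cohort tests "
          f"({sig['gene_id'].nunique()} genes)")

    snv = snv_association(gly, muts, clin)
    snv.to_csv(ROOT / "assoc_snv.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"SNV scan: {int((snv['adj_p'] < 0.05).sum())} significant tests "
          f"of {len(snv)}")

    roles = pd.read_csv(ROOT / "bundle" / "drivers.tsv", sep="\t").set_index("gene_id")["role"]
    pano = driver_panorama(assoc, roles)
    pano.to_csv(ROOT / "driver_panorama.tsv", sep="\t", index=False, float_format="%.6g")
    top = pano.iloc[0]
    print(f"top driver: {top['gene_id']} ({top['role']}), "
          f"significant in {top['n_significant']} cancer type(s)")

    groups = classify_per_cancer(gly, clin)
    bp = burden_and_ploidy(gly, muts, clin, group_labels=groups)
    bp.to_csv(ROOT / "burden_ploidy.tsv", sep="\t", index=False, float_format="%.6g")
    print(bp.to_string(index=False))


if __name__ == "__main__":
    main()
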