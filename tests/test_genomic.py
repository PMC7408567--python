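"""CNA/SNV/burden associations: calling rules, oracles, planted recovery."""

import numpy as np
import pandas as pd
import pytest

from glycoscape.genomic import (
    burden_and_ploidy,
    call_gain_loss,
    cna_association,
    driver_association,
    driver_panorama,
    snv_association,
    tmb,
)
from glycoscape.io_formats import CNAMatrix


def _cna_from_counts(n_gain, n_loss, n_neutral):
    calls = np.array([[1] * n_gain + [-1] * n_loss + [0] * n_neutral])
    n = calls.shape[1]
    return CNAMatrix(["G1"], [f"S{i}" for i in range(n)], calls)


class TestGainLossCall:
    @pytest.mark.parametrize(
        "n_gain,n_loss,expected",
        [
            (20, 9, "gain"),  # ratio 2.22 > 2
            (4, 2, "ambiguous"),  # ratio exactly 2, not > 2
            (9, 20, "loss"),
            (5, 0, "gain"),  # zero denominator: any nonzero numerator wins
            (0, 3, "loss"),
        ],
    )
    def test_ratio_rule(self, n_gain, n_loss, expected):
        (call,) = call_gain_loss(_cna_from_counts(n_gain, n_loss, 5))
        assert call.call == expected
        assert (call.n_gain, call.n_loss) == (n_gain, n_loss)

    def test_no_alterations_ambiguous_with_undefined_ratio(self):
        (call,) = call_gain_loss(_cna_from_counts(0, 0, 10))
        assert call.call == "ambiguous" and np.isnan(call.ratio)

    def test_symmetric_under_sign_flip(self, rng):
        calls = rng.integers(-1, 2, (20, 30))
        a = call_gain_loss(CNAMatrix([f"G{i}" for i in range(20)],
                                     [f"S{j}" for j in range(30)], calls))
        b = call_gain_loss(CNAMatrix([f"G{i}" for i in range(20)],
                                     [f"S{j}" for j in range(30)], -calls))
        flip = {"gain": "loss", "loss": "gain", "ambiguous": "ambiguous"}
        assert [flip[x.call] for x in a] == [y.call for y in b]


def _assoc_inputs(n=200, n_genes=50, planted_gene="G0", shift=0.5, seed=0,
                  carrier_frac=0.3):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    clin = pd.DataFrame(
        {"sample_id": samples, "cancer_type": "T1", "sample_type": "tumor",
         "stage": "II", "os_time": 100.0, "os_event": 0,
         "aneuploidy_score": 0, "genome_doublings": 0}
    ).set_index("sample_id", drop=False)
    calls = np.zeros((n_genes, n), dtype=int)
    u = rng.random((n_genes, n))
    calls[u < 0.10] = 1
    calls[u > 0.95] = -1
    carriers = rng.random(n) < carrier_frac
    calls[0] = np.where(carriers, 1, 0)
    scores = pd.Series(rng.normal(0, 0.3, n), index=samples)
    scores[carriers] += shift
    cna = CNAMatrix([f"G{i}" for i in range(n_genes)], samples, calls)
    return scores, cna, clin, carriers


class TestCNAAssociation:
    def test_planted_gain_detected_and_directional(self):
        scores, cna, clin, _ = _assoc_inputs()
        res = cna_association(scores, cna, clin)
        hit = res[(res["gene_id"] == "G0") & (res["comparison"] == "gain_vs_neutral")]
        assert len(hit) == 1
        assert hit["adj_p"].iloc[0] < 0.05 and hit["delta_mean_score"].iloc[0] > 0

    def test_bh_applied_within_cohort_only(self):
        # two cancer types with disjoint gene signals: adjustment must not mix
        scores, cna, clin, _ = _assoc_inputs(seed=1)
        clin2 = clin.copy()
        clin2["cancer_type"] = "T2"
        clin2.index = [s + "b" for s in clin2.index]
        clin2["sample_id"] = clin2.index
        cna2 = CNAMatrix(cna.gene_ids, list(clin2.index), cna.calls)
        scores2 = pd.Series(scores.to_numpy(), index=clin2.index)
        both = cna_association(
            pd.concat([scores, scores2]),
            CNAMatrix(cna.gene_ids, cna.sample_ids + list(clin2.index),
                      np.hstack([cna.calls, cna2.calls])),
            pd.concat([clin, clin2]),
        )
        single = cna_association(scores, cna, clin)
        merged = both[both["cancer_type"] == "T1"].set_index(["gene_id", "comparison"])
        for _, row in single.iterrows():
            assert merged.loc[(row["gene_id"], row["comparison"]), "adj_p"] == pytest.approx(
                row["adj_p"]
            )

    def test_small_arm_skipped(self):
        scores, cna, clin, _ = _assoc_inputs(seed=2)
        res = cna_association(scores, cna, clin, min_altered=10**6)
        assert len(res) == 0


class TestSNVAssociation:
    def _mutations(self, samples, gene, carriers, nonsyn=True):
        return pd.DataFrame(
            {"sample_id": [s for s, c in zip(samples, carriers) if c],
             "gene_id": gene, "nonsynonymous": nonsyn}
        )

    def test_planted_mutation_effect_detected(self):
        scores, _, clin, carriers = _assoc_inputs(seed=3)
        muts = self._mutations(clin.index, "MUT1", carriers)
        res = snv_association(scores, muts, clin)
        assert res.loc[res["gene_id"] == "MUT1", "adj_p"].iloc[0] < 0.05

    def test_synonymous_only_gene_not_tested(self):
        scores, _, clin, carriers = _assoc_inputs(seed=4)
        muts = self._mutations(clin.index, "SYN1", carriers, nonsyn=False)
        res = snv_association(scores, muts, clin)
        assert "SYN1" not in set(res["gene_id"])

    def test_all_mutated_gene_skipped(self):
        scores, _, clin, _ = _assoc_inputs(seed=5)
        muts = self._mutations(clin.index, "ALL1", [True] * len(clin))
        res = snv_association(scores, muts, clin)
        assert "ALL1" not in set(res["gene_id"])

    def test_multiplicity_collapsed_to_presence(self):
        scores, _, clin, carriers = _assoc_inputs(seed=6)
        muts = self._mutations(clin.index, "MUT1", carriers)
        doubled = pd.concat([muts, muts])  # two records per carrier
        res1 = snv_association(scores, muts, clin)
        res2 = snv_association(scores, doubled, clin)
        assert res1["p"].iloc[0] == pytest.approx(res2["p"].iloc[0])


class TestPanorama:
    def test_recount_oracle(self):
        rng = np.random.default_rng(7)
        types = [f"C{i}" for i in range(25)]
        rows = []
        for ct in types:
            for gene, comparison in (("ONC1", "gain_vs_neutral"),
                                     ("SUP1", "loss_vs_neutral")):
                rows.append({"gene_id": gene, "cancer_type": ct,
                             "comparison": comparison,
                             "delta_mean_score": rng.normal(),
                             "p": rng.random(), "adj_p": 1.0,
                             "n_altered": 10, "n_reference": 50})
        assoc = pd.DataFrame(rows)
        roles = pd.Series({"ONC1": "oncogene", "SUP1": "suppressor"})
        pano = driver_panorama(assoc, roles)
        for _, row in pano.iterrows():
            comparison = ("gain_vs_neutral" if row["role"] == "oncogene"
                          else "loss_vs_neutral")
            expect = int(
                (assoc[(assoc["gene_id"] == row["gene_id"])
                       & (assoc["comparison"] == comparison)]["p"] < 0.05).sum()
            )
            assert row["n_significant"] == expect

    def test_null_counts_zero_sorted_by_name(self):
        assoc = pd.DataFrame(
            {"gene_id": ["B", "A"], "cancer_type": "T1",
             "comparison": ["gain_vs_neutral"] * 2, "delta_mean_score": [0.0, 0.0],
             "p": [0.9, 0.8], "adj_p": [1.0, 1.0], "n_altered": 5, "n_reference": 5}
        )
        roles = pd.Series({"A": "oncogene", "B": "oncogene"})
        pano = driver_panorama(assoc, roles)
        assert pano["n_significant"].tolist() == [0, 0]
        assert pano["gene_id"].tolist() == ["A", "B"]

    def test_unannotated_driver_rejected(self):
        scores, cna, clin, _ = _assoc_inputs(seed=8)
        roles = pd.Series({"G0": "mystery"})
        with pytest.raises(ValueError, match="oncogene"):
            driver_association(scores, cna, clin, roles)


class TestBurdenPloidy:
    def test_tmb_counts_only_nonsynonymous(self):
        muts = pd.DataFrame(
            {"sample_id": ["A"] * 10, "gene_id": [f"G{i}" for i in range(10)],
             "nonsynonymous": [True] * 7 + [False] * 3}
        )
        assert tmb(muts)["A"] == 7

    def test_planted_aneuploidy_correlation_recovered(self):
        rng = np.random.default_rng(9)
        n = 300
        clin = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(n)], "cancer_type": "T1",
             "sample_type": "tumor", "stage": "II", "os_time": 1.0, "os_event": 0,
             "genome_doublings": rng.integers(0, 3, n)}
        ).set_index("sample_id", drop=False)
        scores = pd.Series(rng.normal(size=n), index=clin.index)
        clin["aneuploidy_score"] = np.round(
            10 + 3 * (0.4 * scores + np.sqrt(1 - 0.16) * rng.normal(size=n))
        )
        muts = pd.DataFrame({"sample_id": ["S0"], "gene_id": ["G1"],
                             "nonsynonymous": [True]})
        res = burden_and_ploidy(scores, muts, clin)
        assert abs(res["aneuploidy_rho"].iloc[0] - 0.4) < 0.12

    def test_identical_doubling_classes_null(self):
        rng = np.random.default_rng(10)
        n = 120
        clin = pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(n)], "cancer_type": "T1",
             "sample_type": "tumor", "stage": "II", "os_time": 1.0, "os_event": 0,
             "aneuploidy_score": 5, "genome_doublings": rng.integers(0, 3, n)}
        ).set_index("sample_id", drop=False)
        scores = pd.Series(np.zeros(n), index=clin.index)
        muts = pd.DataFrame({"sample_id": ["S0"], "gene_id": ["G1"],
                             "nonsynonymous": [True]})
        res = burden_and_ploidy(scores, muts, clin)
        assert res["doubling_p"].iloc[0] == 1.0
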