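"""Transcriptome screen: DE rules, recurrence, ranking, quadrants."""

import numpy as np
import pandas as pd
import pytest

from glycoscape.cohort import GroupLabels, classify_by_score
from glycoscape.gsva import ScoreTable
from glycoscape.io_formats import ExpressionMatrix
from glycoscape.screen import (
    candidate_rank,
    de_genes,
    diff_signature_enrichment,
    quadrant_stratify,
    recurrent_genes,
)


def _labels(samples, n_high, n_low):
    lab = pd.Series("mid", index=samples)
    lab[samples[:n_high]] = "high"
    lab[samples[-n_low:]] = "low"
    return GroupLabels(labels=lab, q=0.3, eligible=True, n_high=n_high, n_low=n_low)


class TestDiffEnrichment:
    def test_planted_correlated_signature_flagged(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(100)]
        g = rng.normal(size=100)
        other = 0.8 * g + 0.6 * rng.normal(size=100)  # second program, r = 0.8
        st = ScoreTable(samples, ["glycolysis22", "other"],
                        np.column_stack([np.tanh(g / 2), np.tanh(other / 2)]), {})
        gl = classify_by_score(st.column("glycolysis22"), q=0.3, min_group=5)
        res = diff_signature_enrichment(st, gl).set_index("signature")
        assert res.loc["other", "enriched"] and res.loc["other", "delta"] > 0
        # the defining signature is positively enriched by construction
        assert res.loc["glycolysis22", "delta"] > 0

    def test_null_labels_rarely_significant(self):
        rng = np.random.default_rng(2)
        n_sig = 0
        n_total = 0
        for rep in range(50):
            samples = [f"S{i}" for i in range(60)]
            st = ScoreTable(samples, [f"sig{k}" for k in range(10)],
                            rng.normal(0, 0.3, (60, 10)), {})
            gl = _labels(samples, 18, 18)
            res = diff_signature_enrichment(st, gl)
            n_sig += int(res["enriched"].sum())
            n_total += len(res)
        assert n_sig / n_total <= 0.07


class TestDEGenes:
    def _matrix(self, rng, n_genes=20, n_per=30, shifted=(), shift=1.2, sd=0.5):
        samples = [f"H{i}" for i in range(n_per)] + [f"L{i}" for i in range(n_per)]
        vals = rng.normal(6, sd, (n_genes, 2 * n_per))
        for g in shifted:
            vals[g, :n_per] += shift
        expr = ExpressionMatrix([f"G{i}" for i in range(n_genes)], samples, vals)
        return expr, _labels(samples, n_per, n_per)

    def test_exactly_planted_genes_pass(self, rng):
        expr, gl = self._matrix(rng, shifted=(2, 5, 11, 17))
        res = de_genes(expr, gl)
        up = set(res.loc[res["direction"] == "up", "gene_id"])
        assert up == {"G2", "G5", "G11", "G17"}

    def test_fold_change_rule_is_conjunctive(self, rng):
        # significant but below 1.5-fold: must be excluded
        expr, gl = self._matrix(rng, shifted=(0,), shift=0.45, sd=0.2)
        res = de_genes(expr, gl).set_index("gene_id")
        assert res.loc["G0", "adj_p"] < 0.05
        assert 2.0 ** abs(res.loc["G0", "log2_fold_change"]) < 1.5
        assert res.loc["G0", "direction"] == "ns"

    def test_identical_distributions_not_de(self, rng):
        expr, gl = self._matrix(rng)
        assert (de_genes(expr, gl)["direction"] == "ns").all()

    def test_shuffled_labels_control_fdr(self):
        rng = np.random.default_rng(3)
        false_pos = 0
        n_tests = 0
        for rep in range(100):
            expr, gl = self._matrix(rng, n_genes=40)
            res = de_genes(expr, gl)
            false_pos += int((res["direction"] != "ns").sum())
            n_tests += len(res)
        assert false_pos / n_tests <= 0.07


class TestRecurrence:
    def _de_frame(self, genes_up):
        return pd.DataFrame(
            {"gene_id": list(genes_up), "cancer_type": "x",
             "log2_fold_change": 1.0, "p": 0.001, "adj_p": 0.01,
             "direction": "up"}
        )

    def test_direction_specific_threshold(self):
        de = {f"C{i}": self._de_frame(["A"] if i < 13 else []) for i in range(25)}
        for i in range(13, 25):  # B is 'down' in 13 types: must not count
            de[f"C{i}"] = pd.concat(
                [de[f"C{i}"], self._de_frame(["B"]).assign(direction="down")]
            )
        res = recurrent_genes(de, k=13)
        assert res["gene_id"].tolist() == ["A"]
        assert res["n_up"].iloc[0] == 13

    def test_k_one_equals_union(self):
        de = {"C1": self._de_frame(["A", "B"]), "C2": self._de_frame(["B", "C"])}
        res = recurrent_genes(de, k=1)
        assert set(res["gene_id"]) == {"A", "B", "C"}

    def test_k_exceeding_types_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            recurrent_genes({"C1": self._de_frame([])}, k=2)


class TestCandidateRank:
    def test_planted_regulator_outranks_decoys(self):
        rng = np.random.default_rng(4)
        wins = 0
        for rep in range(20):
            n = 150
            samples = [f"S{i}" for i in range(n)]
            latent = rng.normal(size=n)
            scores = pd.Series(np.tanh(latent / 2), index=samples)
            n_genes = 51
            vals = rng.normal(5, 1, (n_genes, n))
            vals[0] = 5 + 0.8 * latent + 0.6 * rng.normal(size=n)
            expr = ExpressionMatrix(
                ["REG"] + [f"D{i}" for i in range(50)], samples, vals
            )
            res = candidate_rank({"T1": expr}, scores, ["REG"] + [f"D{i}" for i in range(50)])
            wins += res["gene_id"].iloc[0] == "REG"
        assert wins >= 18  # >= 90% of replicates

    def test_tie_breaks_by_gene_name_and_missing_listed(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(20)]
        vals = rng.normal(size=(1, 20))
        expr = ExpressionMatrix(["X"], samples, vals)
        # two candidates referencing the same expression row -> identical rho
        expr2 = ExpressionMatrix(["A", "B"], samples, np.vstack([vals, vals]))
        scores = pd.Series(rng.normal(size=20), index=samples)
        res = candidate_rank({"T1": expr2}, scores, ["B", "A", "GONE"])
        assert res["gene_id"].tolist()[:2] == ["A", "B"]
        assert res.loc[res["gene_id"] == "GONE", "missing"].iloc[0]


class TestQuadrants:
    def test_four_distinct_samples_one_per_quadrant(self):
        samples = list("abcd")
        hyp = pd.Series([0.1, 0.2, 0.8, 0.9], index=samples)
        expr = ExpressionMatrix(["P4HA1"], samples, [[1.0, 9.0, 2.0, 8.0]])
        quad, _ = quadrant_stratify(hyp, expr, "P4HA1")
        assert sorted(quad.labels) == ["H+G+", "H+G-", "H-G+", "H-G-"]

    def test_membership_matches_double_sort_oracle(self):
        rng = np.random.default_rng(6)
        samples = [f"S{i}" for i in range(10)]
        hyp = pd.Series(rng.normal(size=10), index=samples)
        gvals = rng.normal(size=(1, 10))
        expr = ExpressionMatrix(["P4HA1"], samples, gvals)
        quad, _ = quadrant_stratify(hyp, expr, "P4HA1")
        order_h = sorted(samples, key=lambda s: (hyp[s], s))
        h_minus, h_plus = order_h[:5], order_h[5:]
        g = pd.Series(gvals[0], index=samples)
        for stratum, members in (("H+", h_plus), ("H-", h_minus)):
            order_g = sorted(members, key=lambda s: (g[s], s))
            for s in order_g[: len(members) // 2]:
                assert quad.labels[s] == stratum + "G-"
            for s in order_g[len(members) // 2:]:
                assert quad.labels[s] == stratum + "G+"

    def test_quadrant_sizes_balanced_within_stratum(self, rng):
        for n in (7, 12, 25):
            samples = [f"S{i}" for i in range(n)]
            hyp = pd.Series(rng.normal(size=n), index=samples)
            expr = ExpressionMatrix(["X"], samples, rng.normal(size=(1, n)))
            quad, _ = quadrant_stratify(hyp, expr, "X")
            counts = quad.labels.value_counts()
            for stratum in ("H+", "H-"):
                sizes = [counts.get(stratum + "G+", 0), counts.get(stratum + "G-", 0)]
                assert abs(sizes[0] - sizes[1]) <= 1

    def test_amplifier_gene_model_puts_hplus_gplus_highest(self):
        # the gene boosts the hypoxia->glycolysis coupling when high
        rng = np.random.default_rng(7)
        wins = 0
        for rep in range(50):
            n = 200
            samples = [f"S{i}" for i in range(n)]
            h = rng.normal(size=n)
            gene = rng.normal(size=n)
            gly = 0.5 * h + 0.5 * gene * (h > np.median(h)) + 0.3 * rng.normal(size=n)
            hyp = pd.Series(h, index=samples)
            expr = ExpressionMatrix(["AMP"], samples, gene[None, :])
            quad, summary = quadrant_stratify(
                hyp, expr, "AMP", targets={"gly": pd.Series(gly, index=samples)}
            )
            top = summary.set_index("quadrant")["gly_mean"].idxmax()
            wins += top == "H+G+"
        assert wins >= 45

    def test_absent_gene_rejected(self):
        samples = list("abcd")
        hyp = pd.Series([1.0, 2.0, 3.0, 4.0], index=samples)
        expr = ExpressionMatrix(["X"], samples, [[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(KeyError, match="NOPE"):
            quadrant_stratify(hyp, expr, "NOPE")
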