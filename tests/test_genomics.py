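"""TMB, mutation spectra, somatic interaction and association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from timequad.genomics import (
    compute_tmb,
    interaction_table,
    mutation_frequency,
    mutation_group_association,
    mutation_matrix,
    somatic_interaction,
)


def maf_from_counts(counts: dict[str, int], gene="TP53", cls="Missense_Mutation"):
    rows = []
    for sample, k in counts.items():
        rows += [(gene, sample, cls)] * k
    return pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    )


def fisher_two_sided_oracle(a, b, c, d):
    """Minimum-likelihood two-sided Fisher p by hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestComputeTmb:
    @pytest.mark.parametrize("n_mut, expected", [(38, 1.0), (380, 10.0)])
    def test_exome_normalization(self, n_mut, expected):
        maf = maf_from_counts({"s1": n_mut})
        out = compute_tmb(maf, ["s1"])
        assert out.loc["s1", "tmb"] == expected
        assert out.loc["s1", "counted_mutations"] == n_mut

    def test_sample_absent_from_maf_gets_zero(self):
        out = compute_tmb(maf_from_counts({"s1": 5}), ["s1", "s2"])
        assert out.loc["s2", "tmb"] == 0.0

    def test_noncoding_classes_not_counted(self):
        maf = pd.concat(
            [
                maf_from_counts({"s1": 3}, cls="Missense_Mutation"),
                maf_from_counts({"s1": 2}, cls="Silent"),
                maf_from_counts({"s1": 4}, cls="Intron"),
            ]
        )
        out = compute_tmb(maf, ["s1"])
        assert out.loc["s1", "counted_mutations"] == 5  # silent counts, intron not

    def test_unknown_classification_warns_and_excluded(self):
        maf = maf_from_counts({"s1": 1}, cls="Banana")
        with pytest.warns(UserWarning, match="Banana"):
            out = compute_tmb(maf, ["s1"])
        assert out.loc["s1", "counted_mutations"] == 0

    def test_scales_inversely_with_exome_size(self):
        maf = maf_from_counts({"s1": 19})
        assert compute_tmb(maf, ["s1"], exome_mb=19).loc["s1", "tmb"] == 1.0


class TestMutationFrequency:
    def test_quarter_mutated(self):
        maf = maf_from_counts({"s1": 1}, gene="G")
        mm = mutation_matrix(maf, [f"s{i}" for i in range(1, 5)])
        subtypes = pd.Series("I", index=mm.index)
        freq, altered = mutation_frequency(mm, subtypes, top_k=1)
        assert freq.loc["G", "I"] == 0.25
        assert altered["I"] == 0.25

    def test_all_zero_matrix(self):
        mm = pd.DataFrame(0, index=["s1", "s2"], columns=["G"])
        freq, altered = mutation_frequency(mm, pd.Series("II", index=mm.index), top_k=1)
        assert freq.loc["G", "II"] == 0.0

    def test_empty_subtype_reports_nan(self):
        mm = pd.DataFrame([[1], [0]], index=["s1", "s2"], columns=["G"])
        subtypes = pd.Series(["I", "I"], index=mm.index)
        freq, altered = mutation_frequency(mm, subtypes, top_k=1)
        assert np.isnan(freq.loc["G", "III"])
        assert np.isnan(altered["III"])

    def test_recovers_planted_per_subtype_rates(self, rng):
        # binomial sampling oracle at cohort-scale per-subtype rates
        rates = {"I": 0.24, "II": 0.41, "III": 0.51, "IV": 0.29}
        n_per = 800
        rows, labels = [], {}
        for label, rate in rates.items():
            for i in range(n_per):
                s = f"{label}_{i}"
                labels[s] = label
                if rng.random() < rate:
                    rows.append(("TP53", s, "Missense_Mutation"))
        maf = pd.DataFrame(
            rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
        )
        samples = list(labels)
        mm = mutation_matrix(maf, samples)
        freq, _ = mutation_frequency(mm, pd.Series(labels), top_k=1)
        for label, rate in rates.items():
            assert freq.loc["TP53", label] == pytest.approx(rate, abs=0.04)


class TestSomaticInteraction:
    @staticmethod
    def _mm_from_flags(fa, fb):
        idx = [f"s{i}" for i in range(len(fa))]
        return pd.DataFrame({"A": fa, "B": fb}, index=idx)

    def test_perfect_cooccurrence_p_matches_enumeration(self):
        mm = self._mm_from_flags([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        (res,) = somatic_interaction(mm, ["A", "B"])
        assert res.direction == "co-occurrence"
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_independent_genes_near_null(self, rng):
        fa = rng.random(1000) < 0.5
        fb = rng.random(1000) < 0.5
        (res,) = somatic_interaction(self._mm_from_flags(fa.astype(int), fb.astype(int)), ["A", "B"])
        assert abs(np.log(res.odds_ratio)) < 0.3
        assert res.p_value > 0.01

    def test_gene_paired_with_itself_errors(self):
        mm = self._mm_from_flags([1, 0] * 5, [0, 1] * 5)
        with pytest.raises(ValueError, match="itself|duplicate"):
            somatic_interaction(mm, ["A", "A"])

    def test_absent_gene_errors(self):
        mm = self._mm_from_flags([1, 0] * 5, [0, 1] * 5)
        with pytest.raises(ValueError, match="MISSING"):
            somatic_interaction(mm, ["A", "MISSING"])

    def test_symmetric_in_gene_order(self, rng):
        mm = pd.DataFrame(
            rng.integers(0, 2, size=(40, 3)),
            index=[f"s{i}" for i in range(40)],
            columns=["A", "B", "C"],
        )
        fwd = {frozenset((r.gene_a, r.gene_b)): r.p_value
               for r in somatic_interaction(mm, ["A", "B", "C"])}
        rev = {frozenset((r.gene_a, r.gene_b)): r.p_value
               for r in somatic_interaction(mm, ["C", "B", "A"])}
        assert fwd.keys() == rev.keys()
        for pair in fwd:
            assert fwd[pair] == pytest.approx(rev[pair], rel=1e-12)

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 10, size=4)
            n = a + b + c + d
            if n < 10:
                continue
            flags_a = [1] * (a + b) + [0] * (c + d)
            flags_b = [1] * a + [0] * b + [1] * c + [0] * d
            mm = self._mm_from_flags(flags_a, flags_b)
            (res,) = somatic_interaction(mm, ["A", "B"])
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), rel=1e-9
            )

    def test_interaction_table_has_bh_qvalues(self, rng):
        mm = pd.DataFrame(
            rng.integers(0, 2, size=(30, 4)),
            index=[f"s{i}" for i in range(30)],
            columns=list("ABCD"),
        )
        tbl = interaction_table(somatic_interaction(mm, list("ABCD")))
        assert len(tbl) == 6
        assert (tbl["q_value"] >= tbl["p_value"] - 1e-12).all()


class TestGroupAssociation:
    @staticmethod
    def _mm(mut_flags):
        idx = [f"s{i}" for i in range(len(mut_flags))]
        return pd.DataFrame({"G": mut_flags}, index=idx), idx

    def test_identical_proportions_p_one(self):
        mm, idx = self._mm([1] * 10 + [0] * 10 + [1] * 10 + [0] * 10)
        flags = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        out = mutation_group_association(mm, "G", flags)
        assert out["p_value"] == pytest.approx(1.0)

    def test_perfect_association_tiny_p(self):
        mm, idx = self._mm([1] * 20 + [0] * 20)
        flags = pd.Series(["a"] * 20 + ["b"] * 20, index=idx)
        out = mutation_group_association(mm, "G", flags)
        assert out["p_value"] < 1e-9
        assert out["proportions"] == {"a": 1.0, "b": 0.0}

    def test_fisher_fallback_on_sparse_table(self):
        mm, idx = self._mm([1, 0, 0, 0, 0, 0, 1, 0, 0, 0])
        flags = pd.Series(["a"] * 5 + ["b"] * 5, index=idx)
        out = mutation_group_association(mm, "G", flags)
        assert out["test"] == "fisher"

    def test_planted_enrichment_is_powered(self, rng):
        hits = 0
        reps = 30
        for _ in range(reps):
            mut = np.concatenate(
                [rng.random(200) < 0.6, rng.random(200) < 0.3]
            ).astype(int)
            idx = [f"s{i}" for i in range(400)]
            mm = pd.DataFrame({"G": mut}, index=idx)
            flags = pd.Series(["a"] * 200 + ["b"] * 200, index=idx)
            out = mutation_group_association(mm, "G", flags)
            hits += out["p_value"] < 0.001
        assert hits >= int(0.95 * reps)

    def test_empty_group_errors(self):
        mm, idx = self._mm([1, 0] * 5)
        flags = pd.Series(["a"] * 10, index=idx)
        with pytest.raises(ValueError, match="two non-empty"):
            mutation_group_association(mm, "G", flags)
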