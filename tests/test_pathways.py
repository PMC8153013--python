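"""Differential expression contract, gene/pathway scores and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from timequad.io import ExpressionMatrix
from timequad.pathways import (
    SUBTYPES,
    de_all_subtypes,
    differential_expression,
    enrich,
    gene_scores,
    mean_log2fc,
    pathway_scores,
)


def counts_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit="counts"
    )


def de_tables(spec: dict[str, dict[str, float]], genes: list[str]):
    """Build DEResult-style tables from {gene: {subtype: log2FC}} (DEG where set)."""
    out = {}
    for k in SUBTYPES:
        lfc = [spec.get(g, {}).get(k, 0.0) for g in genes]
        deg = [k in spec.get(g, {}) for g in genes]
        out[k] = pd.DataFrame(
            {"log2FC": lfc, "p": 0.0, "fdr": 0.0, "deg": deg}, index=genes
        )
    return out


class TestDifferentialExpression:
    def _labels(self, n_k, n_rest):
        idx = [f"S{j}" for j in range(n_k + n_rest)]
        return pd.Series(["I"] * n_k + ["II"] * n_rest, index=idx)

    def test_identical_distributions_not_deg(self, rng):
        counts = counts_matrix(rng.poisson(50, size=(20, 40)))
        res = differential_expression(counts, self._labels(20, 20), "I")
        assert np.all(np.abs(res["log2FC"]) < 1)
        assert not res["deg"].any()

    def test_planted_eightfold_increase_flagged(self, rng):
        hits, lfc_ok = 0, 0
        reps = 20
        for _ in range(reps):
            base = rng.negative_binomial(10, 10 / (10 + 50.0), size=(30, 100))
            base[0, :50] = rng.negative_binomial(10, 10 / (10 + 400.0), size=50)
            counts = counts_matrix(base)
            res = differential_expression(counts, self._labels(50, 50), "I")
            hits += bool(res["deg"].iloc[0])
            lfc_ok += 2.5 <= res["log2FC"].iloc[0] <= 3.5
        assert hits >= int(0.95 * reps)
        assert lfc_ok >= int(0.9 * reps)

    def test_threshold_is_two_not_nearly_two(self, tmp_path):
        # |log2FC| = 1.9 with tiny FDR must not be a DEG; 2.0 must be
        from timequad.pathways import read_de_override

        p = tmp_path / "de.tsv"
        p.write_text(
            "gene\tsubtype\tlog2FC\tFDR\n"
            "G1\tI\t1.9\t0.01\n"
            "G2\tI\t2.0\t0.01\n"
            "G3\tI\t2.5\t0.2\n"
        )
        de = read_de_override(p)
        assert not de["I"].loc["G1", "deg"]
        assert de["I"].loc["G2", "deg"]
        assert not de["I"].loc["G3", "deg"]  # FDR above 0.05

    def test_small_group_rejected(self, rng):
        counts = counts_matrix(rng.poisson(10, size=(5, 10)))
        labels = pd.Series(["I"] * 2 + ["II"] * 8, index=counts.sample_ids)
        with pytest.raises(ValueError, match=">= 3"):
            differential_expression(counts, labels, "I")


class TestGenePathwayScores:
    def test_mean_log2fc_single_subtype_deg(self):
        de = de_tables({"G1": {"I": 8.0}}, ["G1"])
        assert mean_log2fc(de)["G1"] == pytest.approx(2.0)

    def test_mean_log2fc_all_four_equal(self):
        de = de_tables({"G1": {k: 4.0 for k in SUBTYPES}}, ["G1"])
        assert mean_log2fc(de)["G1"] == pytest.approx(4.0)

    def test_mean_log2fc_no_deg_is_zero(self):
        de = de_tables({"G1": {}}, ["G1"])
        assert mean_log2fc(de)["G1"] == 0.0

    def test_gene_score_single_subtype(self):
        de = de_tables({"G1": {"I": 8.0}}, ["G1"])
        s = gene_scores(de)
        assert s.loc["G1", "I"] == pytest.approx(4.0)  # 8 / 2
        assert (s.loc["G1", ["II", "III", "IV"]] == 0).all()

    def test_gene_score_symmetric_case(self):
        de = de_tables({"G1": {k: 4.0 for k in SUBTYPES}}, ["G1"])
        np.testing.assert_allclose(gene_scores(de).loc["G1"].values, 1.0)

    def test_sign_cancelling_gene_excluded(self):
        de = de_tables({"G1": {"I": 4.0, "II": -4.0}}, ["G1"])
        with pytest.warns(UserWarning, match="zero mean"):
            s = gene_scores(de)
        assert "G1" not in s.index

    def test_single_gene_pathway_deg_only_in_one_subtype(self, toy):
        fx = toy["eq123"]
        scores = gene_scores(fx["de_results"])
        pw = pathway_scores(fx["pathways"], scores)
        np.testing.assert_allclose(pw.loc["P1"].values, [1.0, 0.0, 0.0, 0.0])

    def test_symmetric_gene_quarter_each(self):
        de = de_tables({"G1": {k: 4.0 for k in SUBTYPES}}, ["G1"])
        pw = pathway_scores({"P": ["G1"]}, gene_scores(de))
        np.testing.assert_allclose(pw.loc["P"].values, 0.25)

    def test_matches_brute_force_double_loop(self, rng):
        genes = [f"G{i}" for i in range(60)]
        spec = {}
        for g in genes:
            ks = rng.choice(list(SUBTYPES), size=rng.integers(0, 5), replace=False)
            entry = {k: float(rng.uniform(2, 6) * rng.choice([-1, 1])) for k in ks}
            if entry:
                spec[g] = entry
        de = de_tables(spec, genes)
        scores = gene_scores(de)
        pathways = {
            f"P{j}": list(rng.choice(genes, size=rng.integers(2, 12), replace=False))
            for j in range(8)
        }
        got = pathway_scores(pathways, scores)
        # brute-force double loop over pathways, subtypes and member genes
        for name, members in pathways.items():
            if name not in got.index:
                continue
            per_k = {}
            for k in SUBTYPES:
                total = 0.0
                for g in members:
                    if g not in spec or k not in spec[g]:
                        continue
                    eff = {kk: spec[g].get(kk, 0.0) for kk in SUBTYPES}
                    mean = sum(eff.values()) / 4.0
                    if mean == 0:
                        continue
                    total += abs(eff[k]) / abs(mean)
                per_k[k] = total
            denom = sum(per_k.values())
            for k in SUBTYPES:
                assert got.loc[name, k] == pytest.approx(per_k[k] / denom, abs=1e-12)

    def test_row_normalization_sums_to_one(self, rng):
        genes = [f"G{i}" for i in range(30)]
        spec = {g: {str(rng.choice(list(SUBTYPES))): 3.0} for g in genes}
        de = de_tables(spec, genes)
        pw = pathway_scores({"P": genes}, gene_scores(de))
        assert pw.loc["P"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_scores(self):
        spec = {"G1": {"I": 3.0, "II": 5.0}, "G2": {"III": -4.0}}
        genes = ["G1", "G2"]
        pw1 = pathway_scores({"P": genes}, gene_scores(de_tables(spec, genes)))
        scaled = {g: {k: 2.5 * v for k, v in d.items()} for g, d in spec.items()}
        pw2 = pathway_scores({"P": genes}, gene_scores(de_tables(scaled, genes)))
        np.testing.assert_allclose(pw1.values, pw2.values, atol=1e-12)


class TestEnrich:
    def test_pathway_equal_to_deg_list_kept(self):
        universe = [f"G{i}" for i in range(30)]
        degs = universe[:5]
        out = enrich(degs, {"P": degs}, universe).set_index("pathway")
        assert bool(out.loc["P", "kept"])
        assert out.loc["P", "p_value"] == pytest.approx(
            float(hypergeom.sf(4, 30, 5, 5)), rel=1e-12
        )

    def test_small_overlap_rejected_despite_tiny_p(self):
        universe = [f"G{i}" for i in range(1000)]
        degs = universe[:2]
        out = enrich(degs, {"P": universe[:2]}, universe).set_index("pathway")
        assert out.loc["P", "overlap"] == 2
        assert not bool(out.loc["P", "kept"])  # overlap < 3 regardless of p

    def test_empty_deg_list_gives_no_keeps(self):
        universe = [f"G{i}" for i in range(10)]
        out = enrich([], {"P": universe[:4]}, universe)
        assert not out["kept"].any()

    def test_p_values_match_hypergeometric_enumeration(self, rng):
        universe = [f"G{i}" for i in range(200)]
        degs = list(rng.choice(universe, size=25, replace=False))
        db = {
            f"P{j}": list(rng.choice(universe, size=20, replace=False))
            for j in range(10)
        }
        out = enrich(degs, db, universe).set_index("pathway")
        for name, members in db.items():
            k = len(set(members) & set(degs))
            expected = float(hypergeom.sf(k - 1, 200, len(members), 25))
            assert out.loc[name, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich(["X"], {"P": ["A"]}, ["A", "B"])
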