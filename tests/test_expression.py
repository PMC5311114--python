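"""Fold changes, motif-count bins, shift tests and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gatareg import expression as ex
from gatareg import simulate as sim
from gatareg.expression import (
    Contrast,
    ExpressionMatrix,
    FoldChangeVector,
    GeneSetCollection,
    bin_by_motif_count,
    enrich,
    gene_set_shift_test,
    log2_fold_change,
    motif_promoter_summary,
    top_n_genes,
)
from gatareg.motifs import count_matrix, interval_label
from gatareg.diagnostics import hypergeom_oracle_p


def toy_matrix(values: dict[str, list[float]], conditions=None) -> ExpressionMatrix:
    fpkm = pd.DataFrame(values).T
    fpkm.columns = [f"s{i}" for i in range(fpkm.shape[1])]
    half = fpkm.shape[1] // 2
    meta = pd.DataFrame(
        {
            "strain": ["mut"] * half + ["WT"] * half,
            "condition": (conditions or ["c"] * fpkm.shape[1]),
            "replicate": list(range(half)) + list(range(half)),
        },
        index=fpkm.columns,
    )
    return ExpressionMatrix(fpkm=fpkm, samples=meta)


MUT_VS_WT = Contrast(("mut", None), ("WT", None))


class TestExpressionMatrix:
    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            toy_matrix({"g": [-1.0, 1.0]})

    def test_unknown_group_rejected(self):
        em = toy_matrix({"g": [1.0, 1.0]})
        with pytest.raises(ValueError):
            em.group_samples("nope")

    def test_tsv_roundtrip(self, tmp_path):
        em = toy_matrix({"g1": [3.0, 1.0], "g2": [0.5, 2.0]})
        sim.write_expression_tsv(em, tmp_path / "e.tsv", tmp_path / "m.tsv")
        back = ExpressionMatrix.from_tsv(tmp_path / "e.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.fpkm, em.fpkm, check_names=False)


class TestLog2FoldChange:
    def test_arithmetic(self):
        em = toy_matrix({"g": [14.0, 1.0]})
        lfc = log2_fold_change(em, MUT_VS_WT, pseudocount=1e-9)
        assert lfc.lfc["g"] == pytest.approx(math.log2(14.0), abs=1e-6)

    def test_antisymmetry_exact(self):
        em = toy_matrix({"g1": [5.0, 2.0], "g2": [0.0, 7.0], "g3": [1.0, 1.0]})
        fwd = log2_fold_change(em, MUT_VS_WT).lfc
        rev = log2_fold_change(em, Contrast(("WT", None), ("mut", None))).lfc
        assert (fwd + rev == 0).all()

    def test_fourteen_fold_gene_recovered(self):
        em = toy_matrix({"dga1": [140.0, 140.0, 10.0, 10.0]})
        lfc = log2_fold_change(em, MUT_VS_WT)
        assert 2 ** lfc.lfc["dga1"] == pytest.approx(14.0, rel=0.01)

    def test_pseudocount_keeps_zero_fpkm_finite(self):
        em = toy_matrix({"g": [0.0, 0.0]})
        assert log2_fold_change(em, MUT_VS_WT).lfc["g"] == 0.0

    def test_mean_ratio_aggregation(self):
        em = toy_matrix({"g": [8.0, 2.0, 4.0, 1.0]})
        a = log2_fold_change(em, MUT_VS_WT, 1e-9, "mean_fpkm").lfc["g"]
        b = log2_fold_change(em, MUT_VS_WT, 1e-9, "mean_ratio").lfc["g"]
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(1.0, abs=1e-6)

    def test_bad_pseudocount(self):
        with pytest.raises(ValueError):
            log2_fold_change(toy_matrix({"g": [1, 1]}), MUT_VS_WT, 0.0)


def make_lfc(values: dict[str, float]) -> FoldChangeVector:
    return FoldChangeVector(MUT_VS_WT, pd.Series(values, dtype=float), 0.1)


class TestBinByMotifCount:
    def test_degenerate_all_category_zero(self, small_fixture):
        genome, genes, truth, _ = small_fixture
        no_site_genes = [
            g for g in genes if not truth.motif_sites[g.gene_id]["GATAA"]
        ]
        wcm = count_matrix(genome, no_site_genes, sim.DEFAULT_MOTIFS[0])
        lfc = make_lfc({g.gene_id: float(i) for i, g in enumerate(no_site_genes)})
        bins = bin_by_motif_count(lfc, wcm)
        overall = lfc.lfc.mean()
        for b in bins:
            if b.category == 0:
                assert b.mean_delta == pytest.approx(overall)
                assert b.n == len(no_site_genes)
            else:
                assert b.n == 0 and math.isnan(b.mean_delta)

    def test_weighted_mean_identity(self, small_fixture):
        genome, genes, truth, expr = small_fixture
        eff = truth.effects
        lfc = ex.log2_fold_change(
            expr,
            Contrast((eff["mutant_strain"], None), ((eff["wt_strain"]), None)),
        )
        wcm = count_matrix(genome, genes, sim.DEFAULT_MOTIFS[0])
        bins = bin_by_motif_count(lfc, wcm)
        overall = lfc.lfc.mean()
        for iv in wcm.intervals:
            sub = [b for b in bins if b.interval == iv and b.n > 0]
            weighted = sum(b.mean_delta * b.n for b in sub) / sum(b.n for b in sub)
            assert weighted == pytest.approx(overall)

    def test_category_counts_conserved_across_intervals(self, small_fixture):
        genome, genes, _, _ = small_fixture
        wcm = count_matrix(genome, genes, sim.DEFAULT_MOTIFS[0])
        lfc = make_lfc({g.gene_id: 0.0 for g in genes})
        bins = bin_by_motif_count(lfc, wcm)
        totals = {}
        for b in bins:
            totals[b.interval] = totals.get(b.interval, 0) + b.n
        assert set(totals.values()) == {len(genes)}

    def test_empty_overlap_rejected(self, small_fixture):
        genome, genes, _, _ = small_fixture
        wcm = count_matrix(genome, genes[:5], sim.DEFAULT_MOTIFS[0])
        with pytest.raises(ValueError):
            bin_by_motif_count(make_lfc({"absent": 1.0}), wcm)

    def test_planted_effect_recovery(self, small_fixture):
        genome, genes, truth, expr = small_fixture
        eff = truth.effects
        lfc = ex.log2_fold_change(
            expr, Contrast((eff["mutant_strain"], None), (eff["wt_strain"], None))
        )
        wcm = count_matrix(genome, genes, sim.DEFAULT_MOTIFS[0])
        beta = eff["beta"]["GATAA"]
        sigma = eff["sigma"]
        reps = eff["replicates"]
        bins = [b for b in bin_by_motif_count(lfc, wcm) if b.interval == (-200, 0)]
        for b in bins:
            if b.n == 0:
                continue
            se = sigma * math.sqrt(2 / reps) / math.sqrt(b.n)
            assert b.mean_delta == pytest.approx(beta * b.category, abs=4 * se + 0.02)


class TestMotifPromoterSummary:
    def test_concatenates_per_motif_tables(self, small_fixture):
        genome, genes, truth, expr = small_fixture
        eff = truth.effects
        lfc = ex.log2_fold_change(
            expr, Contrast((eff["mutant_strain"], None), (eff["wt_strain"], None))
        )
        counts = {
            m.name: count_matrix(genome, genes, m) for m in sim.DEFAULT_MOTIFS
        }
        table = motif_promoter_summary(lfc, counts)
        assert set(table.motif) == {"GATAA", "GYGGGG"}
        single = ex.bins_to_frame(
            bin_by_motif_count(lfc, counts["GATAA"]), motif="GATAA"
        )
        pd.testing.assert_frame_equal(
            table[table.motif == "GATAA"].reset_index(drop=True), single
        )

    def test_responsive_vs_unresponsive_motif(self, small_fixture):
        genome, genes, truth, expr = small_fixture
        eff = truth.effects
        lfc = ex.log2_fold_change(
            expr, Contrast((eff["mutant_strain"], None), (eff["wt_strain"], None))
        )
        counts = {
            m.name: count_matrix(genome, genes, m) for m in sim.DEFAULT_MOTIFS
        }
        table = motif_promoter_summary(lfc, counts)
        gataa = table[(table.motif == "GATAA") & (table.interval == "-200:0")
                      & (table.n > 0)]
        diffs = np.diff(gataa.sort_values("category").mean_delta.to_numpy())
        assert (diffs > 0).all()  # planted effect is monotone in category


def exact_mwu_oracle(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = 0.0
    for xi in x:
        for yi in y:
            u_obs += (xi > yi) + 0.5 * (xi == yi)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += (xi > yi) + 0.5 * (xi == yi)
        us.append(u)
    us = np.array(us)
    eps = 1e-9
    p_ge = (us >= u_obs - eps).mean()
    p_le = (us <= u_obs + eps).mean()
    return min(1.0, 2 * min(p_ge, p_le))


class TestShiftTest:
    def test_extreme_separation_maximal_u(self):
        genes = {f"g{i:02d}": float(i) for i in range(18)}
        lfc = make_lfc(genes)
        top = {f"g{i:02d}" for i in range(14, 18)}
        res = gene_set_shift_test(lfc, top, set(genes))
        assert res["U"] == 4 * 14
        assert res["direction"] == 1
        assert res["p"] == pytest.approx(exact_mwu_oracle(
            np.arange(14, 18, dtype=float), np.arange(14, dtype=float)
        ))

    def test_exact_p_matches_enumeration(self, rng):
        for _ in range(5):
            vals = rng.normal(size=12)
            genes = {f"g{i}": float(v) for i, v in enumerate(vals)}
            lfc = make_lfc(genes)
            members = {f"g{i}" for i in rng.choice(12, size=4, replace=False)}
            res = gene_set_shift_test(lfc, members, set(genes))
            x = np.array([genes[g] for g in sorted(members)])
            y = np.array([genes[g] for g in sorted(set(genes) - members)])
            assert res["method"] == "exact"
            assert res["p"] == pytest.approx(exact_mwu_oracle(x, y), abs=1e-12)

    def test_empty_set_rejected(self):
        lfc = make_lfc({"g": 1.0})
        with pytest.raises(ValueError):
            gene_set_shift_test(lfc, set(), {"g"})

    def test_null_calibration_small(self, rng):
        """Type-I error near alpha on a reduced null simulation."""
        hits = 0
        n_sims = 300
        genes = [f"g{i}" for i in range(400)]
        for _ in range(n_sims):
            lfc = make_lfc(dict(zip(genes, rng.normal(size=400))))
            members = set(rng.choice(genes, size=40, replace=False))
            res = gene_set_shift_test(lfc, members, set(genes))
            hits += res["p"] < 0.05
        assert 0.02 <= hits / n_sims <= 0.09


class TestTopN:
    def test_n_exceeds_population(self):
        lfc = make_lfc({f"g{i}": float(i) for i in range(10)})
        assert len(top_n_genes(lfc, 500)) == 10

    def test_tie_broken_by_gene_id(self):
        lfc = make_lfc({"b": 1.0, "a": 1.0, "c": 2.0})
        assert top_n_genes(lfc, 3) == ["c", "a", "b"]

    def test_direction_down(self):
        lfc = make_lfc({"a": 1.0, "b": -2.0, "c": 0.0})
        assert top_n_genes(lfc, 2, "down") == ["b", "c"]


class TestEnrich:
    def _collection(self, N=20, K=5):
        genes = [f"u{i:02d}" for i in range(N)]
        return genes, GeneSetCollection(
            universe=set(genes), sets={"S": set(genes[:K])}
        )

    def test_null_enrichment_is_one(self):
        genes, coll = self._collection(N=20, K=5)
        rows = enrich(genes[:4][:1] + genes[5:8], coll)  # k/n = 1/4 = K/N
        assert rows[0].fold_enrichment == pytest.approx(1.0)

    def test_universe_against_itself(self):
        genes, coll = self._collection(N=20, K=5)
        coll.sets["ALL"] = set(genes)
        rows = {r.set_name: r for r in enrich(genes, coll)}
        assert rows["ALL"].fold_enrichment == pytest.approx(1.0)
        assert rows["ALL"].p_raw == pytest.approx(1.0)

    def test_p_raw_matches_combinatorial_oracle(self):
        genes, coll = self._collection(N=20, K=5)
        gene_list = genes[:3] + genes[5:6]  # k=3, n=4
        row = enrich(gene_list, coll)[0]
        assert row.p_raw == pytest.approx(hypergeom_oracle_p(20, 5, 4, 3), abs=1e-12)

    def test_bonferroni_multiplication(self):
        genes = [f"u{i:02d}" for i in range(40)]
        sets = {f"S{i}": set(genes[i:i + 4]) for i in range(10)}
        coll = GeneSetCollection(universe=set(genes), sets=sets)
        for row in enrich(genes[:6], coll):
            assert row.p_corrected == min(1.0, row.p_raw * 10)

    def test_zero_hit_sets_retained(self):
        genes, coll = self._collection(N=20, K=5)
        rows = enrich(genes[10:14], coll)
        assert rows[0].k == 0 and rows[0].fold_enrichment == 0.0

    def test_list_outside_universe_rejected(self):
        _, coll = self._collection()
        with pytest.raises(ValueError):
            enrich(["zz"], coll)

    def test_gene_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection(universe={"a"}, sets={"S": {"a", "b"}})


class TestGeneSetIO:
    def test_two_column_tsv(self, tmp_path):
        path = tmp_path / "sets.tsv"
        path.write_text("S1\ta\nS1\tb\nS2\tc\nS2\tzz\n")
        coll = GeneSetCollection.from_tsv(path, {"a", "b", "c"})
        assert coll.sets == {"S1": {"a", "b"}, "S2": {"c"}}

    def test_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\ta\tb\nS2\tdesc\tc\n")
        coll = GeneSetCollection.from_gmt(path, {"a", "b", "c"})
        assert coll.sets == {"S1": {"a", "b"}, "S2": {"c"}}
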