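"""Gene classification, signature clustering, and summaries."""

import numpy as np
import pytest

from mpadecomp import (
    DataError,
    beta_sign_summary,
    classify_all,
    classify_gene,
    cluster_signatures,
    decompose,
    summarize_clusters,
)
from mpadecomp.decomposition import BipartiteRelation

from conftest import record


def _relations(gene_modules: dict[str, list[str]], module_phens: dict[str, list[str]]):
    gm_edges = {(g, m) for g, mods in gene_modules.items() for m in mods}
    mp_edges = {(m, p) for m, phens in module_phens.items() for p in phens}
    gm = BipartiteRelation(
        "GM", gene_modules.keys(), module_phens.keys(), gm_edges
    )
    mp = BipartiteRelation(
        "MP", module_phens.keys(), {p for _, p in mp_edges}, mp_edges
    )
    return gm, mp


class TestClassifyGene:
    def test_one_multi_phenotype_module_is_type1(self):
        gm, mp = _relations({"g": ["m1"]}, {"m1": ["P1", "P2"]})
        cls = classify_gene("g", gm, mp)
        assert cls.mpa_class == "TYPE1" and not cls.complex
        assert cls.n_modules == 1 and cls.n_phenotypes == 2

    def test_two_singleton_modules_is_plain_type2(self):
        gm, mp = _relations({"g": ["m1", "m2"]}, {"m1": ["P1"], "m2": ["P2"]})
        cls = classify_gene("g", gm, mp)
        assert cls.mpa_class == "TYPE2" and not cls.complex

    def test_multi_phenotype_member_module_makes_type2_complex(self):
        gm, mp = _relations(
            {"g": ["m1", "m2"]}, {"m1": ["P1", "P2"], "m2": ["P3"]}
        )
        cls = classify_gene("g", gm, mp)
        assert cls.mpa_class == "TYPE2" and cls.complex
        assert cls.n_phenotypes == 3

    def test_single_phenotype_module_is_spa(self):
        gm, mp = _relations({"g": ["m1"]}, {"m1": ["P1"]})
        assert classify_gene("g", gm, mp).mpa_class == "SPA"

    def test_absent_gene_is_an_error(self):
        gm, mp = _relations({"g": ["m1"]}, {"m1": ["P1"]})
        with pytest.raises(DataError):
            classify_gene("ghost", gm, mp)

    def test_classes_partition_genes(self, synthetic_run):
        _, _, _, run = synthetic_run
        classes = classify_all(run.gp, run.gm, run.mp)
        counts = {"SPA": 0, "TYPE1": 0, "TYPE2": 0}
        for cls in classes.values():
            counts[cls.mpa_class] += 1
            if cls.complex:
                assert cls.mpa_class == "TYPE2"
        total_genes = len(set(run.gp.left) | set(run.gm.left))
        assert sum(counts.values()) == total_genes == len(classes)


class TestClusterSignatures:
    def test_genes_with_same_two_modules_form_one_cluster(self):
        gm, mp = _relations(
            {"gA": ["m1", "m2"], "gB": ["m1", "m2"]},
            {"m1": ["P1"], "m2": ["P2"]},
        )
        (cluster,) = cluster_signatures(gm, mp)
        assert cluster.genes == {"gA", "gB"}
        assert cluster.signature == {"m1", "m2"}

    def test_distinct_module_sets_give_singletons(self):
        gm, mp = _relations(
            {"gA": ["m1", "m2"], "gB": ["m2", "m3"]},
            {"m1": ["P1"], "m2": ["P2"], "m3": ["P3"]},
        )
        clusters = cluster_signatures(gm, mp)
        assert sorted(c.size for c in clusters) == [1, 1]

    def test_planted_signatures_recovered_as_planted_groups(self):
        rng = np.random.default_rng(8)
        module_phens = {f"m{i}": [f"P{i}a", f"P{i}b"] for i in range(7)}
        planted = {}
        gene_modules = {}
        for i in range(50):
            sig = frozenset(
                f"m{j}" for j in rng.choice(7, size=rng.integers(2, 4), replace=False)
            )
            gene_modules[f"g{i:02d}"] = sorted(sig)
            planted.setdefault(sig, set()).add(f"g{i:02d}")
        gm, mp = _relations(gene_modules, module_phens)
        clusters = cluster_signatures(gm, mp)
        assert {frozenset(c.genes) for c in clusters} == {
            frozenset(g) for g in planted.values()
        }

    def test_exact_and_mcl_clustering_agree(self, synthetic_run):
        _, _, _, run = synthetic_run
        exact = {frozenset(c.genes) for c in cluster_signatures(run.gm, run.mp)}
        mcl = {
            frozenset(c.genes)
            for c in cluster_signatures(run.gm, run.mp, method="mcl")
        }
        assert exact == mcl

    def test_cluster_members_share_identical_class(self, synthetic_run):
        _, _, _, run = synthetic_run
        classes = classify_all(run.gp, run.gm, run.mp)
        for cluster in run.clusters:
            member_classes = {
                (classes[g].mpa_class, classes[g].complex) for g in cluster.genes
            }
            assert len(member_classes) == 1


class TestSummaries:
    def test_two_gene_cluster_summary_row(self):
        gm, mp = _relations(
            {"gA": ["m1", "m2"], "gB": ["m1", "m2"]},
            {"m1": ["P1"], "m2": ["P2"]},
        )
        clusters = cluster_signatures(gm, mp)
        summary = summarize_clusters(clusters, gm, mp)
        row = summary.loc[2]
        assert row["n_clusters"] == 1
        assert row["mean_modules"] == 2.0
        assert row["mean_phenotypes"] == 2.0

    def test_all_singletons_histogram_mass_at_one(self):
        gm, mp = _relations(
            {"gA": ["m1"], "gB": ["m2"]}, {"m1": ["P1", "P2"], "m2": ["P2", "P3"]}
        )
        summary = summarize_clusters(cluster_signatures(gm, mp), gm, mp)
        assert list(summary.index) == [1]
        assert summary.loc[1, "n_clusters"] == 2

    def test_summary_matches_brute_force_recomputation(self, synthetic_run):
        _, _, _, run = synthetic_run
        summary = summarize_clusters(run.clusters, run.gm, run.mp)
        sizes = sorted({c.size for c in run.clusters})
        assert list(summary.index) == sizes
        for size in sizes:
            members = [c for c in run.clusters if c.size == size]
            assert summary.loc[size, "n_clusters"] == len(members)
            mods = [
                run.gm.degree(g) for c in members for g in c.genes
            ]
            assert summary.loc[size, "mean_modules"] == pytest.approx(
                np.mean(mods)
            )


class TestBetaSignSummary:
    def test_all_negative_betas_have_zero_positive_counts(self, synthetic_run):
        from mpadecomp import AssociationRecord

        truth, significant, genes, run = synthetic_run
        negated = [
            AssociationRecord(
                r.snp_id, r.chrom, r.pos, r.phenotype_id, r.p_value, -abs(r.beta)
            )
            for r in significant
        ]
        table = beta_sign_summary(negated, run.classes, run.snp_gene_map)
        assert set(table.index) == {"SPA", "TYPE1", "TYPE2"}
        assert (table["n_pos"] == 0).all()
        assert table["n_neg"].sum() > 0

    def test_hand_counted_signs_in_type1_gene(self, type1_type2_fixture):
        records, genes = type1_type2_fixture
        from mpadecomp import AssociationRecord

        signed = [
            AssociationRecord(r.snp_id, r.chrom, r.pos, r.phenotype_id, r.p_value,
                              beta)
            for r, beta in zip(records, [0.3, -0.1, -0.4, -0.2])
        ]
        run = decompose(signed, genes)
        table = beta_sign_summary(signed, run.classes, run.snp_gene_map)
        assert table.loc["TYPE1", "n_pos"] == 1
        assert table.loc["TYPE1", "n_neg"] == 1
        assert table.loc["TYPE2", "n_neg"] == 2
        assert int(table.to_numpy().sum()) == 4

    def test_observed_sign_bias_within_binomial_bounds(self, synthetic_run):
        truth, significant, genes, run = synthetic_run
        table = beta_sign_summary(significant, run.classes, run.snp_gene_map)
        n_neg = table["n_neg"].sum()
        n = table.to_numpy().sum()
        # planted sign bias 0.8: observed fraction within 99% binomial band
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(n_neg / n - 0.8) < 2.58 * se + 0.02
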