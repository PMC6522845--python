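"""Profile matrix, Proportional Similarity, modules, and the GP = GM o MP
identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpadecomp import (
    DataError,
    build_gp,
    build_modules,
    build_mp,
    build_profile_matrix,
    build_snp_network,
    decompose,
    identify_mpa_genes,
    map_snps_to_genes,
    proportional_similarity,
    verify_decomposition,
)
from mpadecomp.decomposition import BipartiteRelation

from conftest import record


def _profile(rows: dict[str, list[int]], phenotypes: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=phenotypes, dtype="int8"
    ).sort_index()


class TestProfileMatrix:
    def test_snp_with_two_hits_gives_row_of_ones(self, type1_type2_fixture):
        records, genes = type1_type2_fixture
        mapping = map_snps_to_genes(records, genes)
        matrix = build_profile_matrix(records[:2], mapping)
        assert matrix.shape == (1, 2)
        assert matrix.to_numpy().tolist() == [[1, 1]]

    def test_unmapped_snp_row_absent(self):
        from mpadecomp import GeneModel

        genes = [GeneModel("g", "Chr01", 100, 200)]
        records = [record("Chr01_150", "P1"), record("Chr09_5", "P2")]
        mapping = map_snps_to_genes(records, genes)
        matrix = build_profile_matrix(records, mapping)
        assert list(matrix.index) == ["Chr01_150"]

    def test_three_by_two_incidence_matches_hand_table(self):
        from mpadecomp import GeneModel

        genes = [GeneModel("g", "Chr01", 1, 1000)]
        records = [
            record("Chr01_10", "P1"),
            record("Chr01_20", "P1"),
            record("Chr01_20", "P2"),
            record("Chr01_30", "P2"),
        ]
        mapping = map_snps_to_genes(records, genes)
        matrix = build_profile_matrix(records, mapping)
        expected = _profile(
            {"Chr01_10": [1, 0], "Chr01_20": [1, 1], "Chr01_30": [0, 1]},
            ["P1", "P2"],
        )
        pd.testing.assert_frame_equal(matrix, expected)

    def test_no_mapped_significant_snps_is_an_error(self):
        from mpadecomp import GeneModel

        genes = [GeneModel("g", "Chr05", 1, 10)]
        records = [record("Chr01_10", "P1")]
        mapping = map_snps_to_genes(records, genes)
        with pytest.raises(DataError, match="no in-gene"):
            build_profile_matrix(records, mapping)


class TestProportionalSimilarity:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 0, 1], [1, 0, 1], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 1, 0], [0, 1, 1], 0.5),
            ([2.0, 1.0], [1.0, 3.0], 2 * (1 + 1) / 7),
        ],
    )
    def test_hand_computed_values(self, x, y, expected):
        assert proportional_similarity(x, y) == pytest.approx(expected)

    def test_two_zero_profiles_undefined(self):
        with pytest.raises(DataError):
            proportional_similarity([0, 0], [0, 0])

    @given(
        st.integers(2, 12).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 1), min_size=n, max_size=n),
                st.lists(st.integers(0, 1), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_bounds_and_binary_identity_law(self, pair):
        x, y = pair
        if sum(x) == 0 or sum(y) == 0:
            return
        ps = proportional_similarity(x, y)
        assert ps == pytest.approx(proportional_similarity(y, x))
        assert 0.0 <= ps <= 1.0
        assert (ps == pytest.approx(1.0)) == (x == y)


class TestSnpNetworkAndModules:
    def test_identical_profiles_edge_weight_one(self):
        matrix = _profile({"s1": [1, 0], "s2": [1, 0]}, ["P1", "P2"])
        (edge,) = build_snp_network(matrix)
        assert edge.weight == 1.0

    def test_disjoint_profiles_zero_edge_omitted(self):
        matrix = _profile({"s1": [1, 0], "s2": [0, 1]}, ["P1", "P2"])
        assert build_snp_network(matrix) == []

    def test_weights_match_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        rows = {
            f"s{i}": list(rng.integers(0, 2, 4)) for i in range(5)
        }
        for row in rows.values():
            if sum(row) == 0:
                row[0] = 1
        matrix = _profile(rows, ["P1", "P2", "P3", "P4"])
        edges = {
            (e.snp_a, e.snp_b): e.weight for e in build_snp_network(matrix)
        }
        snps = sorted(rows)
        for i, a in enumerate(snps):
            for b in snps[i + 1:]:
                expected = proportional_similarity(rows[a], rows[b])
                assert edges.get((a, b), 0.0) == pytest.approx(expected)

    def test_equivalence_classes_become_modules(self):
        matrix = _profile(
            {"s1": [1, 0], "s2": [1, 0], "s3": [1, 1]}, ["P1", "P2"]
        )
        modules = build_modules(matrix)
        by_phens = {m.phenotypes: m.snps for m in modules}
        assert by_phens == {
            frozenset({"P1"}): {"s1", "s2"},
            frozenset({"P1", "P2"}): {"s3"},
        }

    def test_singleton_profiles_form_singleton_modules(self):
        matrix = _profile({"s1": [1, 0], "s2": [0, 1]}, ["P1", "P2"])
        modules = build_modules(matrix)
        assert sorted(len(m.snps) for m in modules) == [1, 1]

    def test_one_snp_yields_one_module(self):
        matrix = _profile({"s1": [1, 1]}, ["P1", "P2"])
        (module,) = build_modules(matrix)
        assert module.snps == {"s1"} and module.phenotypes == {"P1", "P2"}

    @pytest.mark.parametrize("seed", range(5))
    def test_mcl_route_equals_exact_partition(self, seed):
        rng = np.random.default_rng(seed)
        n_snps, n_phen = 60, 6
        raw = rng.integers(0, 2, (n_snps, n_phen))
        raw[raw.sum(axis=1) == 0, 0] = 1
        matrix = pd.DataFrame(
            raw.astype("int8"),
            index=[f"s{i:03d}" for i in range(n_snps)],
            columns=[f"P{j}" for j in range(n_phen)],
        )
        exact = {frozenset(m.snps) for m in build_modules(matrix, method="exact")}
        mcl = {frozenset(m.snps) for m in build_modules(matrix, method="mcl")}
        assert exact == mcl

    def test_module_ids_stable_across_runs(self):
        matrix = _profile({"s1": [1, 0], "s2": [1, 1]}, ["P1", "P2"])
        first = [m.module_id for m in build_modules(matrix)]
        second = [m.module_id for m in build_modules(matrix)]
        assert first == second


class TestRelationsAndIdentity:
    def test_mpa_gene_identification(self, type1_type2_fixture):
        records, genes = type1_type2_fixture
        mapping = map_snps_to_genes(records, genes)
        gp = build_gp(records, mapping)
        assert identify_mpa_genes(gp) == {"gene_t1", "gene_t2"}

    def test_gene_with_one_phenotype_not_mpa(self):
        from mpadecomp import GeneModel

        genes = [GeneModel("g", "Chr01", 1, 1000)]
        records = [record("Chr01_10", "P1"), record("Chr01_20", "P1")]
        mapping = map_snps_to_genes(records, genes)
        assert identify_mpa_genes(build_gp(records, mapping)) == frozenset()

    def test_multi_phenotype_module_has_two_mp_edges(self):
        matrix = _profile({"s3": [1, 1]}, ["P1", "P2"])
        mp = build_mp(build_modules(matrix))
        (module_id,) = mp.left
        assert mp.degree(module_id) == 2

    def test_mp_rows_equal_member_snp_profiles(self, synthetic_run):
        _, _, _, run = synthetic_run
        for module in run.modules:
            for snp in module.snps:
                row = run.profile.loc[snp]
                support = frozenset(run.profile.columns[row.to_numpy() == 1])
                assert support == module.phenotypes
                assert run.mp.neighbors(module.module_id) == support

    def test_gm_degrees_type1_vs_type2(self, type1_type2_fixture):
        records, genes = type1_type2_fixture
        run = decompose(records, genes)
        assert run.gm.degree("gene_t1") == 1
        assert run.gm.degree("gene_t2") == 2

    def test_module_spanning_overlapping_genes_links_both(self):
        from mpadecomp import GeneModel

        genes = [
            GeneModel("g1", "Chr01", 1, 500),
            GeneModel("g2", "Chr01", 400, 900),
        ]
        # the shared SNP at 450 plus a second phenotype to make both genes MPA
        records = [
            record("Chr01_450", "P1"),
            record("Chr01_100", "P2"),
            record("Chr01_800", "P2"),
        ]
        run = decompose(records, genes)
        shared = [m for m in run.modules if "Chr01_450" in m.snps]
        assert len(shared) == 1
        assert run.gm.neighbors("g1") >= {shared[0].module_id}
        assert run.gm.neighbors("g2") >= {shared[0].module_id}

    def test_identity_holds_on_synthetic_run(self, synthetic_run):
        _, _, _, run = synthetic_run
        assert run.identity_ok
        ok, mismatches = verify_decomposition(run.gp, run.gm, run.mp)
        assert ok and mismatches == []

    def test_deleting_mp_edge_breaks_identity_with_named_mismatch(
        self, synthetic_run
    ):
        _, _, _, run = synthetic_run
        # pick an MP edge some gene depends on uniquely, so deleting it
        # must break the reconstruction
        edge = None
        for gene in sorted(run.gm.left):
            modules = run.gm.neighbors(gene)
            for phen in sorted(run.gp.neighbors(gene)):
                covering = [
                    m for m in modules if phen in run.mp.neighbors(m)
                ]
                if len(covering) == 1:
                    edge = (covering[0], phen)
                    break
            if edge:
                break
        assert edge is not None
        pruned = BipartiteRelation(
            "MP", run.mp.left, run.mp.right, run.mp.edges - {edge}
        )
        ok, mismatches = verify_decomposition(run.gp, run.gm, pruned)
        assert not ok
        assert any(phen == edge[1] and kind == "missing" for _, phen, kind in mismatches)

    def test_gm_module_labels_must_exist_in_mp(self, synthetic_run):
        _, _, _, run = synthetic_run
        bad_gm = BipartiteRelation(
            "GM",
            run.gm.left,
            list(run.gm.right) + ["M_ghost"],
            set(run.gm.edges) | {(sorted(run.gm.left)[0], "M_ghost")},
        )
        with pytest.raises(DataError, match="absent from MP"):
            verify_decomposition(run.gp, bad_gm, run.mp)

    def test_gp_degree_equals_union_of_mp_rows_per_gene(self, synthetic_run):
        _, _, _, run = synthetic_run
        for gene in run.gm.left:
            union = set()
            for module in run.gm.neighbors(gene):
                union |= run.mp.neighbors(module)
            assert run.gp.degree(gene) == len(union)

    def test_modules_partition_restricted_snps(self, synthetic_run):
        _, _, _, run = synthetic_run
        seen = [snp for m in run.modules for snp in m.snps]
        assert len(seen) == len(set(seen))
        phenotype_sets = [m.phenotypes for m in run.modules]
        assert len(phenotype_sets) == len(set(phenotype_sets))
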