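"""Core decomposition of gene-phenotype associations into powerset space.

The GWAS profile matrix ``M`` is a binary SNP x phenotype matrix: ``M[i,j]
= 1`` iff SNP *i* (residing in a gene) is significantly associated with
phenotype *j*. SNPs whose profiles are identical — Proportional Similarity
exactly 1 — are collapsed into *association modules*; each module is a
distinct observed element of the powerset of phenotypes, and the modules
form the axes of powerset space. Two bipartite relations then decompose
the gene-phenotype (GP) relation: gene-module (GM) links a gene to every
module containing one of its SNPs, and module-phenotype (MP) links a
module to the phenotypes shared by all its SNPs. Over multi-phenotype
association (MPA) genes the boolean identity ``GP = GM o MP`` holds by
construction and is verified explicitly after every run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, DataError
from .ingest import AssociationRecord, SnpGeneMap
from .mcl import mcl_cluster


@dataclass(frozen=True)
class SimilarityEdge:
    """Proportional-Similarity edge between two SNP profiles."""

    snp_a: str
    snp_b: str
    weight: float


@dataclass(frozen=True)
class AssociationModule:
    """A maximal group of SNPs sharing one phenotype profile.

    Equivalently one observed element of the powerset of phenotypes: every
    member SNP is significantly associated with exactly ``phenotypes``.
    """

    module_id: str
    snps: frozenset[str]
    phenotypes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.snps or not self.phenotypes:
            raise DataError(f"module {self.module_id}: empty SNP or phenotype set")


class BipartiteRelation:
    """A binary relation between two typed node partitions (GP, GM, MP...)."""

    def __init__(
        self,
        role: str,
        left: Iterable[str],
        right: Iterable[str],
        edges: Iterable[tuple[str, str]],
    ):
        self.role = role
        self.left: tuple[str, ...] = tuple(sorted(set(left)))
        self.right: tuple[str, ...] = tuple(sorted(set(right)))
        self.edges: frozenset[tuple[str, str]] = frozenset(edges)
        left_set, right_set = set(self.left), set(self.right)
        self._fwd: dict[str, set[str]] = {node: set() for node in self.left}
        self._rev: dict[str, set[str]] = {node: set() for node in self.right}
        for l, r in self.edges:
            if l not in left_set or r not in right_set:
                raise DataError(
                    f"{role}: edge ({l!r}, {r!r}) outside declared partitions"
                )
            self._fwd[l].add(r)
            self._rev[r].add(l)

    def neighbors(self, node: str) -> frozenset[str]:
        if node in self._fwd:
            return frozenset(self._fwd[node])
        if node in self._rev:
            return frozenset(self._rev[node])
        raise KeyError(node)

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def to_matrix(self) -> tuple[sp.csr_matrix, tuple[str, ...], tuple[str, ...]]:
        """Sparse incidence matrix plus row (left) and column (right) labels."""
        li = {node: i for i, node in enumerate(self.left)}
        ri = {node: i for i, node in enumerate(self.right)}
        rows = [li[l] for l, r in self.edges]
        cols = [ri[r] for l, r in self.edges]
        matrix = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(self.left), len(self.right)),
        )
        return matrix, self.left, self.right

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.edges), columns=["source", "target"]
        ).assign(relation=self.role)

    def __repr__(self) -> str:
        return (
            f"BipartiteRelation({self.role}, |left|={len(self.left)}, "
            f"|right|={len(self.right)}, |edges|={len(self.edges)})"
        )


def build_profile_matrix(
    significant_records: Iterable[AssociationRecord], snp_gene_map: SnpGeneMap
) -> pd.DataFrame:
    """Binary SNP x phenotype GWAS profile matrix from significant records.

    Rows are restricted to SNPs present in ``snp_gene_map`` (SNPs residing
    in gene regions); row and column order is lexicographic. Every row has
    at least one nonzero entry by construction.
    """
    pairs = {
        (r.snp_id, r.phenotype_id)
        for r in significant_records
        if r.snp_id in snp_gene_map.snp_ids
    }
    if not pairs:
        raise DataError("no in-gene significant SNPs")
    snps = sorted({s for s, _ in pairs})
    phens = sorted({p for _, p in pairs})
    matrix = pd.DataFrame(
        np.zeros((len(snps), len(phens)), dtype=np.int8), index=snps, columns=phens
    )
    for s, p in pairs:
        matrix.at[s, p] = 1
    return matrix


def proportional_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Proportional Similarity (Czekanowski) index of two profiles.

    ``PS(X, Y) = 2 * sum_i min(x_i, y_i) / sum_i (x_i + y_i)``, in [0, 1];
    1 iff two binary profiles are identical, 0 iff supports are disjoint.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise DataError("profiles must have equal length")
    if np.any(xv < 0) or np.any(yv < 0):
        raise DataError("profiles must be nonnegative")
    denom = float(xv.sum() + yv.sum())
    if denom == 0.0:
        raise DataError("Proportional Similarity undefined for two zero profiles")
    return float(2.0 * np.minimum(xv, yv).sum() / denom)


def build_gp(
    significant_records: Iterable[AssociationRecord], snp_gene_map: SnpGeneMap
) -> BipartiteRelation:
    """Gene-phenotype relation: gene -> union of its SNPs' phenotype hits."""
    edges: set[tuple[str, str]] = set()
    for rec in significant_records:
        for gene in snp_gene_map.genes_of(rec.snp_id):
            edges.add((gene, rec.phenotype_id))
    genes = {g for g, _ in edges}
    phens = {p for _, p in edges}
    return BipartiteRelation("GP", genes, phens, edges)


def build_snp_phenotype(
    significant_records: Iterable[AssociationRecord],
) -> BipartiteRelation:
    edges = {(r.snp_id, r.phenotype_id) for r in significant_records}
    return BipartiteRelation(
        "SNP-phenotype", {s for s, _ in edges}, {p for _, p in edges}, edges
    )


def identify_mpa_genes(gp_relation: BipartiteRelation) -> frozenset[str]:
    """Genes associated with two or more phenotypes (GP degree >= 2)."""
    return frozenset(
        gene for gene in gp_relation.left if gp_relation.degree(gene) >= 2
    )


def _restricted_matrix(
    profile_matrix: pd.DataFrame, restrict_to_snps: Iterable[str] | None
) -> pd.DataFrame:
    if restrict_to_snps is None:
        return profile_matrix
    restriction = sorted(set(restrict_to_snps))
    missing = set(restriction) - set(profile_matrix.index)
    if missing:
        raise DataError(f"restriction contains unknown SNPs: {sorted(missing)[:5]}")
    if not restriction:
        raise DataError("empty SNP restriction")
    return profile_matrix.loc[restriction]


def build_snp_network(
    profile_matrix: pd.DataFrame,
    restrict_to_snps: Iterable[str] | None = None,
) -> list[SimilarityEdge]:
    """All-vs-all Proportional Similarity network over profile rows.

    Zero-weight pairs (disjoint profiles) are omitted from storage; the
    network is semantically complete with those pairs at weight zero. For
    binary profiles ``sum_i min(x_i, y_i)`` is the dot product, so the
    whole computation is one sparse matrix product.
    """
    matrix = _restricted_matrix(profile_matrix, restrict_to_snps)
    if matrix.shape[0] == 0:
        raise DataError("no SNPs to compare")
    values = sp.csr_matrix(matrix.to_numpy(dtype=np.int64))
    overlap = (values @ values.T).tocoo()
    row_sums = np.asarray(values.sum(axis=1)).ravel()
    snps = list(matrix.index)
    edges = []
    for i, j, shared in zip(overlap.row, overlap.col, overlap.data):
        if i >= j or shared == 0:
            continue
        weight = 2.0 * shared / (row_sums[i] + row_sums[j])
        edges.append(SimilarityEdge(snps[i], snps[j], float(weight)))
    edges.sort(key=lambda e: (e.snp_a, e.snp_b))
    return edges


def _module_id(phenotypes: frozenset[str], taken: set[str]) -> str:
    digest = hashlib.sha1("|".join(sorted(phenotypes)).encode()).hexdigest()[:10]
    base = f"M_{digest}"
    candidate, suffix = base, 0
    while candidate in taken:
        suffix += 1
        candidate = f"{base}.{suffix}"
    taken.add(candidate)
    return candidate


def _modules_from_groups(
    groups: Iterable[frozenset[str]], matrix: pd.DataFrame
) -> list[AssociationModule]:
    taken: set[str] = set()
    modules = []
    for group in sorted(groups, key=lambda g: min(g)):
        member = min(group)
        row = matrix.loc[member]
        phenotypes = frozenset(matrix.columns[row.to_numpy() == 1])
        modules.append(
            AssociationModule(_module_id(phenotypes, taken), group, phenotypes)
        )
    modules.sort(key=lambda m: sorted(m.phenotypes))
    return modules


def build_modules(
    profile_matrix: pd.DataFrame,
    restrict_to_snps: Iterable[str] | None = None,
    method: str = "exact",
    mcl_params: Mapping | None = None,
) -> list[AssociationModule]:
    """Group SNPs into association modules (PS threshold 1).

    For binary profiles PS = 1 is equivalent to identical rows, so the
    threshold is evaluated as exact set equality of profile supports.
    ``method="exact"`` groups rows directly; ``method="mcl"`` prunes the PS
    network to weight-1 edges and clusters the resulting clique graph with
    MCL. The two must agree on every threshold-1 graph; the exact partition
    is the ground truth.
    """
    matrix = _restricted_matrix(profile_matrix, restrict_to_snps)
    if matrix.shape[0] == 0:
        raise DataError("no SNPs to group into modules")

    if method == "exact":
        by_profile: dict[tuple, set[str]] = {}
        for snp, row in zip(matrix.index, matrix.to_numpy()):
            by_profile.setdefault(tuple(row), set()).add(snp)
        groups = [frozenset(g) for g in by_profile.values()]
    elif method == "mcl":
        edges = [
            (e.snp_a, e.snp_b, e.weight)
            for e in build_snp_network(matrix)
            if e.weight == 1.0
        ]
        result = mcl_cluster(edges, nodes=list(matrix.index), **(mcl_params or {}))
        groups = result.clusters
    else:
        raise ConfigError(f"unknown module construction method {method!r}")

    return _modules_from_groups(groups, matrix)


def build_mp(modules: Sequence[AssociationModule]) -> BipartiteRelation:
    """Module-phenotype relation: module -> phenotypes shared by all its SNPs."""
    edges = {
        (module.module_id, phen)
        for module in modules
        for phen in module.phenotypes
    }
    return BipartiteRelation(
        "MP", {m.module_id for m in modules}, {p for _, p in edges}, edges
    )


def build_gm(
    modules: Sequence[AssociationModule], snp_gene_map: SnpGeneMap
) -> BipartiteRelation:
    """Gene-module relation: gene -> modules containing a SNP inside it."""
    edges: set[tuple[str, str]] = set()
    for module in modules:
        for snp in module.snps:
            for gene in snp_gene_map.genes_of(snp):
                edges.add((gene, module.module_id))
    genes = {g for g, _ in edges}
    return BipartiteRelation("GM", genes, {m.module_id for m in modules}, edges)


def verify_decomposition(
    gp: BipartiteRelation, gm: BipartiteRelation, mp: BipartiteRelation
) -> tuple[bool, list[tuple[str, str, str]]]:
    """Check the boolean identity ``GP(g,p) = OR_m [GM(g,m) AND MP(m,p)]``.

    Evaluated over the genes present in GM (by default the MPA genes whose
    SNPs entered module construction). Returns ``(ok, mismatches)`` where
    each mismatch is ``(gene, phenotype, "missing"|"extra")`` — "missing"
    means GP has the edge but the reconstruction does not.
    """
    unknown_modules = set(gm.right) - set(mp.left)
    if unknown_modules:
        raise DataError(
            f"GM references modules absent from MP: {sorted(unknown_modules)[:5]}"
        )
    mismatches: list[tuple[str, str, str]] = []
    for gene in gm.left:
        reconstructed: set[str] = set()
        for module in gm.neighbors(gene):
            reconstructed |= mp.neighbors(module)
        observed = set(gp.neighbors(gene)) if gene in gp.left else set()
        for phen in sorted(observed - reconstructed):
            mismatches.append((gene, phen, "missing"))
        for phen in sorted(reconstructed - observed):
            mismatches.append((gene, phen, "extra"))
    return (not mismatches, mismatches)
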