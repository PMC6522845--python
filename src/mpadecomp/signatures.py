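"""MPA signature classification, signature clustering, and summaries.

A gene's multi-phenotype-association (MPA) signature is its row in the GM
relation — the set of association modules its SNPs fall into:

* Type 1: one module, and that module carries >= 2 phenotypes (a single
  variant associated with several phenotypes).
* Type 2: two or more modules (different variants in the gene associated
  with different phenotype sets). Type 2 takes precedence when both
  patterns co-occur; the ``complex`` flag marks Type 2 genes with at least
  one multi-phenotype member module.
* SPA: single-phenotype association — one module with one phenotype.

Signature clustering groups genes with *identical* module sets (identical
GM rows, i.e. Proportional Similarity 1 in powerset space), exactly or via
MCL on the weight-1 similarity graph.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decomposition import BipartiteRelation
from .errors import ConfigError, DataError
from .ingest import AssociationRecord, SnpGeneMap
from .mcl import mcl_cluster

CLASS_SPA = "SPA"
CLASS_TYPE1 = "TYPE1"
CLASS_TYPE2 = "TYPE2"


@dataclass(frozen=True)
class SignatureClass:
    """Classification of one gene's MPA signature."""

    gene_id: str
    mpa_class: str
    complex: bool
    n_modules: int
    n_phenotypes: int

    @property
    def label(self) -> str:
        """Four-way label separating complex Type 2 genes ('complex')."""
        if self.complex:
            return "complex"
        return self.mpa_class.lower()


@dataclass(frozen=True)
class SignatureCluster:
    """A maximal set of genes sharing an identical module set."""

    cluster_id: str
    genes: frozenset[str]
    signature: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"cluster {self.cluster_id}: empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


def classify_gene(
    gene_id: str, gm: BipartiteRelation, mp: BipartiteRelation
) -> SignatureClass:
    """Classify one gene from its GM neighborhood and module phenotype sets."""
    if gene_id not in set(gm.left):
        raise DataError(f"gene {gene_id!r} absent from GM relation")
    modules = gm.neighbors(gene_id)
    phenotype_union: set[str] = set()
    any_multi = False
    for module in modules:
        phens = mp.neighbors(module)
        phenotype_union |= phens
        if len(phens) >= 2:
            any_multi = True
    n_modules = len(modules)
    if n_modules >= 2:
        mpa_class, is_complex = CLASS_TYPE2, any_multi
    elif any_multi:
        mpa_class, is_complex = CLASS_TYPE1, False
    else:
        mpa_class, is_complex = CLASS_SPA, False
    return SignatureClass(
        gene_id=gene_id,
        mpa_class=mpa_class,
        complex=is_complex,
        n_modules=n_modules,
        n_phenotypes=len(phenotype_union),
    )


def classify_genes(
    gm: BipartiteRelation, mp: BipartiteRelation
) -> dict[str, SignatureClass]:
    """Classify every gene in GM. Total: classes partition the gene set."""
    return {gene: classify_gene(gene, gm, mp) for gene in gm.left}


def classify_all(
    gp: BipartiteRelation, gm: BipartiteRelation, mp: BipartiteRelation
) -> dict[str, SignatureClass]:
    """Classify all genes with hits: GM genes by signature, the rest as SPA.

    Under the default run, module construction is restricted to MPA-gene
    SNPs, so genes present in GP but absent from GM are the
    single-phenotype-association genes.
    """
    classes = classify_genes(gm, mp)
    gm_genes = set(gm.left)
    for gene in gp.left:
        if gene not in gm_genes:
            classes[gene] = SignatureClass(gene, CLASS_SPA, False, 1, 1)
    return classes


def classes_to_frame(classes: Mapping[str, SignatureClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "class": c.mpa_class,
                "complex": c.complex,
                "n_modules": c.n_modules,
                "n_phenotypes": c.n_phenotypes,
            }
            for c in sorted(classes.values(), key=lambda c: c.gene_id)
        ]
    )


def _cluster_id(signature: frozenset[str], taken: set[str]) -> str:
    digest = hashlib.sha1("|".join(sorted(signature)).encode()).hexdigest()[:10]
    base = f"C_{digest}"
    candidate, suffix = base, 0
    while candidate in taken:
        suffix += 1
        candidate = f"{base}.{suffix}"
    taken.add(candidate)
    return candidate


def cluster_signatures(
    gm: BipartiteRelation,
    mp: BipartiteRelation | None = None,
    method: str = "exact",
    include_spa: bool = False,
    mcl_params: Mapping | None = None,
) -> list[SignatureCluster]:
    """Cluster genes by identical module sets (identical GM rows).

    SPA genes are excluded by default (requires ``mp`` to recognize them
    unless every GM gene is MPA); singleton clusters are allowed. With
    ``method="mcl"`` the weight-1 Proportional-Similarity graph over GM
    rows is clustered with MCL; the exact grouping is the ground truth and
    the two must agree.
    """
    if not gm.left:
        raise DataError("GM relation is empty")
    genes = list(gm.left)
    if not include_spa:
        if mp is None:
            raise ConfigError("mp relation required to exclude SPA genes")
        classes = classify_genes(gm, mp)
        genes = [g for g in genes if classes[g].mpa_class != CLASS_SPA]
    if not genes:
        return []

    signatures = {gene: frozenset(gm.neighbors(gene)) for gene in genes}

    if method == "exact":
        by_signature: dict[frozenset[str], set[str]] = {}
        for gene, sig in signatures.items():
            by_signature.setdefault(sig, set()).add(gene)
        groups = [(sig, frozenset(members)) for sig, members in by_signature.items()]
    elif method == "mcl":
        # PS = 1 on binary rows is exact equality of module sets
        edges = []
        ordered = sorted(genes)
        for i, ga in enumerate(ordered):
            for gb in ordered[i + 1 :]:
                if signatures[ga] == signatures[gb]:
                    edges.append((ga, gb, 1.0))
        result = mcl_cluster(edges, nodes=ordered, **(mcl_params or {}))
        groups = [
            (signatures[min(members)], frozenset(members))
            for members in result.clusters
        ]
    else:
        raise ConfigError(f"unknown clustering method {method!r}")

    taken: set[str] = set()
    clusters = [
        SignatureCluster(_cluster_id(sig, taken), members, sig)
        for sig, members in sorted(groups, key=lambda item: min(item[1]))
    ]
    return clusters


def summarize_clusters(
    clusters: Sequence[SignatureCluster],
    gm: BipartiteRelation,
    mp: BipartiteRelation,
) -> pd.DataFrame:
    """Per-cluster-size summary table.

    One row per observed cluster size ``s``: number of clusters of that
    size, mean modules per gene, and mean phenotypes per gene (union of the
    gene's module phenotype sets), averaged over all genes in clusters of
    size ``s``. The ``n_clusters`` column is the full size histogram.
    """
    rows = []
    for cluster in clusters:
        for gene in cluster.genes:
            modules = gm.neighbors(gene)
            phens: set[str] = set()
            for module in modules:
                phens |= mp.neighbors(module)
            rows.append(
                {
                    "size": cluster.size,
                    "cluster_id": cluster.cluster_id,
                    "n_modules": len(modules),
                    "n_phenotypes": len(phens),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["size", "n_clusters", "mean_modules", "mean_phenotypes"]
        ).set_index("size")
    frame = pd.DataFrame(rows)
    summary = frame.groupby("size").agg(
        n_clusters=("cluster_id", "nunique"),
        mean_modules=("n_modules", "mean"),
        mean_phenotypes=("n_phenotypes", "mean"),
    )
    return summary


def beta_sign_summary(
    significant_records: Iterable[AssociationRecord],
    classes: Mapping[str, SignatureClass],
    snp_gene_map: SnpGeneMap,
) -> pd.DataFrame:
    """Counts of positive/negative/zero betas per MPA class.

    Each significant association of a SNP is counted once per gene the SNP
    resides in, under that gene's class. Classes: SPA, TYPE1, TYPE2.
    """
    counts = {
        cls: {"n_pos": 0, "n_neg": 0, "n_zero": 0}
        for cls in (CLASS_SPA, CLASS_TYPE1, CLASS_TYPE2)
    }
    for rec in significant_records:
        for gene in snp_gene_map.genes_of(rec.snp_id):
            if gene not in classes:
                continue
            cls = classes[gene].mpa_class
            if rec.beta > 0:
                counts[cls]["n_pos"] += 1
            elif rec.beta < 0:
                counts[cls]["n_neg"] += 1
            else:
                counts[cls]["n_zero"] += 1
    frame = pd.DataFrame(counts).T
    frame.index.name = "class"
    return frame


def clusters_to_frame(clusters: Sequence[SignatureCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "genes": ",".join(sorted(c.genes)),
                "signature": ",".join(sorted(c.signature)),
            }
            for c in clusters
        ]
    )
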