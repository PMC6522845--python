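"""In-memory orchestration of the full decomposition on significant records.

This is the library-level entry point the CLI, the examples and the tests
share: given significance-filtered association records and gene models it
builds the profile matrix, the GP/GM/MP relations, association modules,
signature classes and clusters, and verifies the decomposition identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import decomposition as dc
from . import signatures as sg
from .ingest import AssociationRecord, GeneModel, SnpGeneMap, map_snps_to_genes


@dataclass
class DecompositionResult:
    """Everything one decomposition run produces."""

    profile: pd.DataFrame
    snp_gene_map: SnpGeneMap
    gp: dc.BipartiteRelation
    snp_phenotype: dc.BipartiteRelation
    mpa_genes: frozenset[str]
    modules: list[dc.AssociationModule]
    gm: dc.BipartiteRelation
    mp: dc.BipartiteRelation
    classes: dict[str, sg.SignatureClass]
    clusters: list[sg.SignatureCluster]
    identity_ok: bool
    identity_mismatches: list[tuple[str, str, str]]

    def summary(self) -> dict:
        """Headline counts for reports."""
        by_class = {"SPA": 0, "TYPE1": 0, "TYPE2": 0}
        n_complex = 0
        for cls in self.classes.values():
            by_class[cls.mpa_class] += 1
            n_complex += int(cls.complex)
        sizes = sorted(c.size for c in self.clusters)
        histogram: dict[int, int] = {}
        for size in sizes:
            histogram[size] = histogram.get(size, 0) + 1
        return {
            "n_snps": int(self.profile.shape[0]),
            "n_phenotypes_with_hits": int(self.profile.shape[1]),
            "n_genes_with_hits": len(self.gp.left),
            "n_mpa_genes": len(self.mpa_genes),
            "n_modules": len(self.modules),
            "n_spa_genes": by_class["SPA"],
            "n_type1_genes": by_class["TYPE1"],
            "n_type2_genes": by_class["TYPE2"],
            "n_complex_genes": n_complex,
            "n_clusters": len(self.clusters),
            "max_cluster_size": max(sizes) if sizes else 0,
            "cluster_size_histogram": histogram,
            "decomposition_identity": self.identity_ok,
        }


def decompose(
    significant_records: Sequence[AssociationRecord],
    genes: Sequence[GeneModel],
    method: str = "exact",
    include_spa: bool = False,
    mcl_params: Mapping | None = None,
) -> DecompositionResult:
    """Run the full decomposition on significance-filtered records.

    By default module construction is restricted to SNPs residing in MPA
    genes (genes with >= 2 associated phenotypes); ``include_spa=True``
    lifts the restriction so the decomposition identity extends to every
    gene with a hit, and SPA genes enter the signature clustering.
    """
    snp_gene_map = map_snps_to_genes(significant_records, genes)
    profile = dc.build_profile_matrix(significant_records, snp_gene_map)
    mapped_records = [
        r for r in significant_records if r.snp_id in snp_gene_map.snp_ids
    ]
    gp = dc.build_gp(mapped_records, snp_gene_map)
    snp_phen = dc.build_snp_phenotype(mapped_records)
    mpa_genes = dc.identify_mpa_genes(gp)

    if include_spa:
        restriction = None
    else:
        restriction = sorted(
            {
                snp
                for gene in mpa_genes
                for snp in snp_gene_map.snps_of(gene)
                if snp in profile.index
            }
        )
    if restriction is not None and not restriction:
        modules = []  # no MPA genes: powerset space is empty
    else:
        modules = dc.build_modules(
            profile,
            restrict_to_snps=restriction,
            method=method,
            mcl_params=mcl_params,
        )
    gm = dc.build_gm(modules, snp_gene_map)
    mp = dc.build_mp(modules)
    classes = sg.classify_all(gp, gm, mp)
    if gm.left:
        clusters = sg.cluster_signatures(
            gm, mp, method=method, include_spa=include_spa, mcl_params=mcl_params
        )
    else:
        clusters = []
    identity_ok, mismatches = dc.verify_decomposition(gp, gm, mp)
    return DecompositionResult(
        profile=profile,
        snp_gene_map=snp_gene_map,
        gp=gp,
        snp_phenotype=snp_phen,
        mpa_genes=mpa_genes,
        modules=modules,
        gm=gm,
        mp=mp,
        classes=classes,
        clusters=clusters,
        identity_ok=identity_ok,
        identity_mismatches=mismatches,
    )
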