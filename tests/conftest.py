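"""Shared fixtures: tiny hand-built topologies and synthetic runs."""

from __future__ import annotations

import pytest

from mpadecomp import (
    AssociationRecord,
    GeneModel,
    decompose,
    emit_associations,
    generate_truth,
    hierarchical_filter,
)


def record(snp_id, phenotype_id, p=1e-12, beta=-0.5):
    chrom, _, pos = snp_id.rpartition("_")
    return AssociationRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=int(pos),
        phenotype_id=phenotype_id,
        p_value=p,
        beta=beta,
    )


@pytest.fixture
def type2_cluster_fixture():
    """Two genes, each holding one SNP per phenotype for the same two
    phenotypes: the worked Type 2 signature cluster topology (two modules,
    one cluster of two genes)."""
    genes = [
        GeneModel("geneA", "Chr12", 1000, 2000),
        GeneModel("geneB", "Chr16", 5000, 6000),
    ]
    records = [
        record("Chr12_1100", "gentisic-acid-2-O-glucoside"),
        record("Chr12_1900", "cis-3-O-caffeoyl-quinate"),
        record("Chr16_5200", "gentisic-acid-2-O-glucoside"),
        record("Chr16_5800", "cis-3-O-caffeoyl-quinate"),
    ]
    return records, genes


@pytest.fixture
def type1_type2_fixture():
    """One Type 1 gene (single SNP hitting two phenotypes) and one Type 2
    gene (two SNPs with one distinct phenotype each)."""
    genes = [
        GeneModel("gene_t1", "Chr13", 100, 900),
        GeneModel("gene_t2", "Chr01", 100, 900),
    ]
    records = [
        record("Chr13_150", "P1"),
        record("Chr13_150", "P2"),
        record("Chr01_200", "P1"),
        record("Chr01_700", "P2"),
    ]
    return records, genes


@pytest.fixture(scope="session")
def synthetic_run():
    """A deterministic mid-size synthetic run through the full path."""
    truth = generate_truth(80, 15, seed=42)
    records, genes = emit_associations(truth)
    significant = hierarchical_filter(records).records
    run = decompose(significant, genes)
    return truth, significant, genes, run
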