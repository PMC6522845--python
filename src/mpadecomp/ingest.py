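"""Reading gene models and GWAS summary statistics; SNP-to-gene mapping.

Coordinates are 1-based inclusive throughout (GFF3 and VCF convention).
A SNP is considered to reside in a gene if ``gene.start <= pos <= gene.end``
on the same chromosome; strand is stored but plays no role in mapping, and a
SNP covered by several overlapping genes maps to all of them.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, DataError, ParseError

#: canonical long-format column names for association tables
LONG_COLUMNS = ("snp_id", "chrom", "pos", "phenotype_id", "p_value", "beta")


@dataclass(frozen=True)
class GeneModel:
    """A gene region: coding sequence plus UTRs, as annotated in the GFF3.

    ``start``/``end`` are 1-based inclusive genomic coordinates with
    ``start <= end``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise DataError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-phenotype association test: p-value and effect size (beta).

    Beta is the estimated effect of one minor-allele dose on the phenotype
    value; its sign says whether the minor allele raises or lowers the
    phenotype.
    """

    snp_id: str
    chrom: str
    pos: int
    phenotype_id: str
    p_value: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise DataError(
                f"record ({self.snp_id}, {self.phenotype_id}): "
                f"p-value {self.p_value} outside (0, 1]"
            )


class SnpGeneMap:
    """Many-to-many relation between SNP ids and the gene regions they lie in."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(pairs)
        snp_to_genes: dict[str, set[str]] = {}
        gene_to_snps: dict[str, set[str]] = {}
        for snp, gene in self.pairs:
            snp_to_genes.setdefault(snp, set()).add(gene)
            gene_to_snps.setdefault(gene, set()).add(snp)
        self._snp_to_genes = {s: frozenset(g) for s, g in snp_to_genes.items()}
        self._gene_to_snps = {g: frozenset(s) for g, s in gene_to_snps.items()}

    def genes_of(self, snp_id: str) -> frozenset[str]:
        return self._snp_to_genes.get(snp_id, frozenset())

    def snps_of(self, gene_id: str) -> frozenset[str]:
        return self._gene_to_snps.get(gene_id, frozenset())

    @property
    def snp_ids(self) -> frozenset[str]:
        return frozenset(self._snp_to_genes)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self._gene_to_snps)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.pairs), columns=["snp_id", "gene_id"])


def _parse_gff3_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in column.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gene_models(source: str | Path | Iterable[str]) -> list[GeneModel]:
    """Parse ``gene`` features from a GFF3 file into :class:`GeneModel` objects.

    Child features (mRNA, exon, UTR, CDS ...) are ignored: the gene span in
    the annotation already covers the UTRs. Coordinates are taken verbatim
    (GFF3 is 1-based inclusive). Raises :class:`ParseError` naming the line
    number on malformed lines, and :class:`DataError` on duplicate gene ids.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as handle:
            return read_gene_models(handle)

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ParseError(
                f"GFF3 line {lineno}: expected 9 tab-separated columns, "
                f"got {len(parts)}"
            )
        if parts[2] != "gene":
            continue
        try:
            start, end = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise ParseError(f"GFF3 line {lineno}: non-integer coordinate") from exc
        attrs = _parse_gff3_attributes(parts[8])
        gene_id = attrs.get("ID") or attrs.get("Name")
        if not gene_id:
            raise ParseError(f"GFF3 line {lineno}: gene feature without ID attribute")
        if gene_id in seen:
            raise DataError(f"duplicate gene id {gene_id!r} (GFF3 line {lineno})")
        seen.add(gene_id)
        try:
            genes.append(GeneModel(gene_id, parts[0], start, end, parts[6]))
        except DataError as exc:
            raise ParseError(f"GFF3 line {lineno}: {exc}") from exc
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal GFF3 (gene features only)."""
    with open(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            handle.write(
                f"{g.chrom}\tmpadecomp\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _frame_to_records(
    frame: pd.DataFrame, phenotype_default: str | None, source_name: str
) -> list[AssociationRecord]:
    records: list[AssociationRecord] = []
    p = pd.to_numeric(frame["p_value"], errors="coerce")
    b = pd.to_numeric(frame["beta"], errors="coerce")
    bad = p.isna() | b.isna()
    if bad.any():
        warnings.warn(
            f"{source_name}: dropped {int(bad.sum())} row(s) with non-numeric "
            "p-value or beta",
            stacklevel=2,
        )
    for idx in frame.index[~bad]:
        row = frame.loc[idx]
        pv = float(p.loc[idx])
        if not (0.0 < pv <= 1.0):
            raise DataError(
                f"{source_name}, row {idx}: p-value {pv} outside (0, 1]"
            )
        phen = phenotype_default
        if phen is None:
            phen = str(row["phenotype_id"])
        records.append(
            AssociationRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                phenotype_id=phen,
                p_value=pv,
                beta=float(b.loc[idx]),
            )
        )
    return records


def read_associations(
    source: str | Path | _io.TextIOBase,
    phenotype_id: str | None = None,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[AssociationRecord]:
    """Read a long-format association table (TSV or CSV with header).

    Expected columns are ``snp_id chrom pos phenotype_id p_value beta``;
    ``columns`` may rename them (mapping canonical -> actual). The phenotype
    id is resolved as: explicit ``phenotype_id`` argument > ``phenotype_id``
    column > filename stem. Rows with non-numeric p or beta are dropped with
    a warning; a p-value outside (0, 1] raises :class:`DataError` naming the
    row.
    """
    name = str(source) if isinstance(source, (str, Path)) else "<stream>"
    frame = pd.read_csv(source, sep=sep, engine="python")
    if columns:
        frame = frame.rename(columns={v: k for k, v in columns.items()})
    needed = ["snp_id", "chrom", "pos", "p_value", "beta"]
    phen_default = phenotype_id
    if phen_default is None and "phenotype_id" not in frame.columns:
        if isinstance(source, (str, Path)):
            phen_default = Path(source).stem
        else:
            raise ConfigError(
                f"{name}: no phenotype_id column and no phenotype id supplied"
            )
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ConfigError(f"{name}: missing required column(s) {missing}")
    return _frame_to_records(frame, phen_default, name)


def read_emmax_ps(
    source: str | Path, phenotype_id: str | None = None
) -> list[AssociationRecord]:
    """Read a per-phenotype EMMAX-style ``.ps`` triplet file.

    Columns (no header): ``snp_id beta p_value``. The phenotype id defaults
    to the filename stem; SNP ids must follow the ``chrom_pos`` convention so
    chromosome and position can be recovered.
    """
    phen = phenotype_id if phenotype_id is not None else Path(source).stem
    frame = pd.read_csv(
        source, sep=r"\s+", header=None, names=["snp_id", "beta", "p_value"]
    )
    chroms, positions = [], []
    for idx, snp in enumerate(frame["snp_id"].astype(str)):
        chrom, _, pos = snp.rpartition("_")
        if not chrom or not pos.isdigit():
            raise ParseError(
                f"{source}, row {idx}: SNP id {snp!r} not in chrom_pos form"
            )
        chroms.append(chrom)
        positions.append(int(pos))
    frame["chrom"] = chroms
    frame["pos"] = positions
    return _frame_to_records(frame, phen, str(source))


def read_association_files(
    paths: Sequence[str | Path], **kwargs
) -> list[AssociationRecord]:
    """Read several association files (long-format or .ps) into one record list."""
    records: list[AssociationRecord] = []
    for path in paths:
        path = Path(path)
        if path.suffix == ".ps":
            records.extend(read_emmax_ps(path, **kwargs))
        else:
            records.extend(read_associations(path, **kwargs))
    return records


def map_snps_to_genes(
    records: Iterable[AssociationRecord], genes: Sequence[GeneModel]
) -> SnpGeneMap:
    """Map each SNP to every gene region containing its position.

    SNPs falling in no gene are simply absent from the map (they never enter
    the profile matrix); an empty map is valid.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        # IntervalTree intervals are half-open; genes are 1-based inclusive.
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end + 1, gene.gene_id
        )
    pairs: set[tuple[str, str]] = set()
    seen_snps: set[str] = set()
    for rec in records:
        if rec.snp_id in seen_snps:
            continue
        seen_snps.add(rec.snp_id)
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for hit in tree.at(rec.pos):
            pairs.add((rec.snp_id, hit.data))
    return SnpGeneMap(pairs)
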