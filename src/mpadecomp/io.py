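"""Standard-format export and import: MatrixMarket matrices with label
sidecars, and SIF / GraphML / TSV network files."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .decomposition import BipartiteRelation
from .errors import ConfigError, DataError

#: node types of each relation role, (left, right)
NODE_TYPES = {
    "GP": ("gene", "phenotype"),
    "GM": ("gene", "module"),
    "MP": ("module", "phenotype"),
    "SNP-phenotype": ("snp", "phenotype"),
}

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def export_matrix(matrix: pd.DataFrame, base_path: str | Path) -> list[Path]:
    """Write a labeled matrix as MatrixMarket plus row/column sidecars.

    Writes ``<base>.mtx`` (coordinate format), ``<base>.rows.txt`` and
    ``<base>.cols.txt`` (one label per line). Empty matrices are rejected.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise DataError("refusing to export an empty matrix")
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    sparse = sp.coo_matrix(np.asarray(matrix, dtype=float))
    mtx = base.with_suffix(".mtx")
    scipy.io.mmwrite(str(mtx), sparse)
    rows = base.with_suffix(".rows.txt")
    cols = base.with_suffix(".cols.txt")
    rows.write_text("".join(f"{label}\n" for label in matrix.index))
    cols.write_text("".join(f"{label}\n" for label in matrix.columns))
    return [mtx, rows, cols]


def import_matrix(base_path: str | Path) -> pd.DataFrame:
    """Re-read a matrix written by :func:`export_matrix`."""
    base = Path(base_path)
    sparse = scipy.io.mmread(str(base.with_suffix(".mtx")))
    rows = base.with_suffix(".rows.txt").read_text().splitlines()
    cols = base.with_suffix(".cols.txt").read_text().splitlines()
    dense = np.asarray(sp.coo_matrix(sparse).todense())
    return pd.DataFrame(dense, index=rows, columns=cols)


def relation_to_matrix_frame(relation: BipartiteRelation) -> pd.DataFrame:
    matrix, rows, cols = relation.to_matrix()
    return pd.DataFrame(matrix.todense(), index=list(rows), columns=list(cols))


def export_network(
    relation: BipartiteRelation, path: str | Path, fmt: str
) -> Path:
    """Export a bipartite relation as SIF, GraphML, or TSV.

    Node types (gene/module/phenotype/snp) are preserved as attributes in
    GraphML and as columns in TSV; the TSV form round-trips losslessly via
    :func:`import_network_tsv`.
    """
    if fmt not in NETWORK_FORMATS:
        raise ConfigError(
            f"unknown network format {fmt!r}; choose from {NETWORK_FORMATS}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    left_type, right_type = NODE_TYPES.get(relation.role, ("left", "right"))
    edges = sorted(relation.edges)

    if fmt == "sif":
        with open(path, "wt") as handle:
            for l, r in edges:
                handle.write(f"{l}\t{relation.role}\t{r}\n")
    elif fmt == "tsv":
        frame = pd.DataFrame(edges, columns=["source", "target"])
        frame["source_type"] = left_type
        frame["target_type"] = right_type
        frame["relation"] = relation.role
        frame.to_csv(path, sep="\t", index=False)
    else:  # graphml
        graph = nx.Graph()
        for node in relation.left:
            graph.add_node(node, kind=left_type, bipartite=0)
        for node in relation.right:
            graph.add_node(node, kind=right_type, bipartite=1)
        for l, r in edges:
            graph.add_edge(l, r, relation=relation.role)
        nx.write_graphml(graph, path)
    return path


def import_network_tsv(path: str | Path) -> BipartiteRelation:
    """Rebuild a bipartite relation from its TSV export."""
    frame = pd.read_csv(path, sep="\t")
    needed = {"source", "target", "relation"}
    if not needed.issubset(frame.columns):
        raise DataError(f"{path}: not a network TSV (missing {needed})")
    roles = frame["relation"].unique()
    if len(roles) != 1:
        raise DataError(f"{path}: mixed relation roles {list(roles)}")
    return BipartiteRelation(
        role=str(roles[0]),
        left=frame["source"].astype(str),
        right=frame["target"].astype(str),
        edges=zip(frame["source"].astype(str), frame["target"].astype(str)),
    )


def export_gene_table(genes: Sequence, path: str | Path) -> None:
    """Write gene models as a TSV table (round-trips all fields)."""
    frame = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    frame.to_csv(path, sep="\t", index=False)


def import_gene_table(path: str | Path):
    from .ingest import GeneModel

    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in frame.itertuples()
    ]
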