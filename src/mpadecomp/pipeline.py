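"""End-to-end pipeline: files in, matrices/networks/reports out.

Orchestrates optional phenotype QC, significance filtering, ingest and
SNP-gene mapping, decomposition, and signature classification/clustering,
writing every matrix and relation in standard formats plus a JSON run
report. Two runs with identical config and inputs produce byte-identical
primary outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from . import qc as qcmod
from . import significance as sig
from .errors import ConfigError, DataError, MpaError
from .ingest import read_association_files, read_gene_models
from .signatures import beta_sign_summary, classes_to_frame, clusters_to_frame, summarize_clusters
from .workflow import DecompositionResult, decompose

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialized into the run manifest."""

    associations: list[Path]
    gff3: Path
    outdir: Path
    phenotype_matrix: Path | None = None
    q1: float = sig.DEFAULT_Q1
    q2: float = sig.DEFAULT_Q2
    sig_mode: str = "hierarchical"
    fixed_threshold: float | None = None
    mad_k: float = qcmod.DEFAULT_K
    min_valid: int = qcmod.DEFAULT_MIN_VALID
    method: str = "exact"
    include_spa: bool = False
    mcl_inflation: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["associations"] = [str(p) for p in self.associations]
        out["gff3"] = str(self.gff3)
        out["outdir"] = str(self.outdir)
        if self.phenotype_matrix is not None:
            out["phenotype_matrix"] = str(self.phenotype_matrix)
        return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunReport:
    """Counts and verdicts of a completed run."""

    config: dict
    counts: dict
    significance: dict
    qc: dict | None
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "counts": self.counts,
                    "significance": self.significance,
                    "qc": self.qc,
                    "outputs": self.outputs,
                },
                indent=2,
                sort_keys=True,
            )
        )


def run_pipeline(config: RunConfig) -> tuple[RunReport, DecompositionResult]:
    """Execute the full pipeline; on failure remove partial outputs.

    Stage order: phenotype QC (optional) -> significance filtering ->
    gene-model ingest and SNP-gene mapping -> decomposition ->
    classification and signature clustering -> export.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        qc_info = None
        if config.phenotype_matrix is not None:
            stage = "phenotype_qc"
            matrix = qcmod.read_phenotype_matrix(config.phenotype_matrix)
            filtered, qc_report = qcmod.filter_metabolites(
                matrix, k=config.mad_k, min_valid=config.min_valid
            )
            qc_report.to_tsv(emit(outdir / "qc_report.tsv"))
            qc_report.to_json(emit(outdir / "qc_report.json"))
            qcmod.write_phenotype_matrix(
                filtered, emit(outdir / "phenotypes_filtered.tsv")
            )
            qc_info = {
                "n_metabolites_in": int(matrix.shape[1]),
                "n_metabolites_kept": int(filtered.shape[1]),
                "n_values_flagged": qc_report.n_flagged,
            }

        stage = "ingest"
        if not config.associations:
            raise ConfigError("no association inputs configured")
        for path in [*config.associations, config.gff3]:
            if not Path(path).exists():
                raise DataError(f"input not found: {path}")
        records = read_association_files(config.associations)
        genes = read_gene_models(config.gff3)

        stage = "significance"
        result = sig.hierarchical_filter(
            records,
            q1=config.q1,
            q2=config.q2,
            mode=config.sig_mode,
            threshold=config.fixed_threshold,
        )
        result.table.to_csv(
            emit(outdir / "associations_annotated.tsv"), sep="\t", index=False
        )
        significant = result.records
        if not significant:
            raise DataError("no significant associations after FDR filtering")

        stage = "decomposition"
        run = decompose(
            significant,
            genes,
            method=config.method,
            include_spa=config.include_spa,
            mcl_params={"inflation": config.mcl_inflation},
        )

        stage = "export"
        mio.export_matrix(run.profile, outdir / "M")
        written += [outdir / "M.mtx", outdir / "M.rows.txt", outdir / "M.cols.txt"]
        for rel, name in ((run.gp, "GP"), (run.gm, "GM"), (run.mp, "MP")):
            if rel.left and rel.right:
                mio.export_matrix(
                    mio.relation_to_matrix_frame(rel), outdir / name
                )
                written += [
                    outdir / f"{name}.mtx",
                    outdir / f"{name}.rows.txt",
                    outdir / f"{name}.cols.txt",
                ]
            mio.export_network(rel, emit(outdir / f"{name}.tsv"), "tsv")
        modules_frame = [
            {
                "module_id": m.module_id,
                "n_snps": len(m.snps),
                "snps": ",".join(sorted(m.snps)),
                "phenotypes": ",".join(sorted(m.phenotypes)),
            }
            for m in run.modules
        ]
        pd.DataFrame(modules_frame).to_csv(
            emit(outdir / "modules.tsv"), sep="\t", index=False
        )
        classes_to_frame(run.classes).to_csv(
            emit(outdir / "classes.tsv"), sep="\t", index=False
        )
        clusters_to_frame(run.clusters).to_csv(
            emit(outdir / "clusters.tsv"), sep="\t", index=False
        )
        summarize_clusters(run.clusters, run.gm, run.mp).to_csv(
            emit(outdir / "cluster_summary.tsv"), sep="\t"
        )
        beta_sign_summary(significant, run.classes, run.snp_gene_map).to_csv(
            emit(outdir / "beta_signs.tsv"), sep="\t"
        )

        stage = "report"
        report = RunReport(
            config=config.to_dict(),
            counts=run.summary(),
            significance=result.metadata(),
            qc=qc_info,
            outputs=sorted(str(p.name) for p in written),
        )
        report.to_json(outdir / "report.json")
        manifest = {
            "config": config.to_dict(),
            "input_checksums": {
                str(p): _checksum(Path(p))
                for p in [*config.associations, config.gff3]
                + ([config.phenotype_matrix] if config.phenotype_matrix else [])
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return report, run
    except MpaError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc
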