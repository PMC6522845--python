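"""Asymmetric-MAD outlier QC for phenotype (metabolite) intensity matrices.

Metabolite intensity distributions are skewed — low intensities are far more
frequent than high ones — so a single symmetric MAD either over-flags the
short tail or under-flags the long one. The approach here computes the
median absolute deviation separately for values below and above the median
(strict inequality: values equal to the median belong to neither tail) and
flags a value as an outlier when it sits more than ``k`` tail-MADs from the
median (default k=5, raw MAD without the 1.4826 normal-consistency factor).

Metabolites measured in too few genotypes are unreliable: after flagging,
any column with fewer than ``min_valid`` non-zero, non-missing, non-flagged
values is excluded (default 100).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: default MAD-distance cutoff for outlier flagging
DEFAULT_K = 5.0
#: default minimum number of non-zero non-outlier values per metabolite
DEFAULT_MIN_VALID = 100


def asymmetric_mad(values: Sequence[float]) -> tuple[float, float, float]:
    """Median plus lower- and upper-tail MADs of ``values``.

    The median is taken over all non-missing values (zeros included); the
    lower MAD is the median of ``|x - med|`` over values strictly below the
    median, the upper MAD likewise over values strictly above. An empty tail
    yields ``nan`` for that side. Raw MAD: no consistency constant applied.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DataError("asymmetric_mad: all values missing")
    med = float(np.median(v))
    lower = v[v < med]
    upper = v[v > med]
    lower_mad = float(np.median(med - lower)) if lower.size else math.nan
    upper_mad = float(np.median(upper - med)) if upper.size else math.nan
    return med, lower_mad, upper_mad


def flag_outliers(values: Sequence[float], k: float = DEFAULT_K) -> np.ndarray:
    """Boolean mask of values more than ``k`` tail-MADs from the median.

    A tail whose MAD is undefined (empty tail) or zero flags nothing on that
    side — with a single extreme point the tail MAD equals the point's own
    distance, so lone extremes in an otherwise empty tail are deliberately
    not flagged. Missing values are never flagged.
    """
    arr = np.asarray(values, dtype=float)
    med, lower_mad, upper_mad = asymmetric_mad(arr)
    mask = np.zeros(arr.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        upper = arr > med
        if upper.any():
            if math.isnan(upper_mad) or upper_mad == 0.0:
                logger.warning(
                    "upper tail MAD undefined or zero; no upper-tail flags"
                )
            else:
                mask |= upper & ((arr - med) / upper_mad > k)
        lower = arr < med
        if lower.any():
            if math.isnan(lower_mad) or lower_mad == 0.0:
                logger.warning(
                    "lower tail MAD undefined or zero; no lower-tail flags"
                )
            else:
                mask |= lower & ((med - arr) / lower_mad > k)
    mask &= ~np.isnan(arr)
    return mask


@dataclass
class ColumnQC:
    """Outlier-QC decisions for one metabolite column."""

    phenotype_id: str
    median: float
    lower_mad: float
    upper_mad: float
    flagged: list[tuple[str, float]]
    n_valid: int
    kept: bool


@dataclass
class OutlierReport:
    """Per-metabolite QC record for a :func:`filter_metabolites` run."""

    k: float
    min_valid: int
    columns: list[ColumnQC] = field(default_factory=list)

    @property
    def kept_ids(self) -> list[str]:
        return [c.phenotype_id for c in self.columns if c.kept]

    @property
    def dropped_ids(self) -> list[str]:
        return [c.phenotype_id for c in self.columns if not c.kept]

    @property
    def n_flagged(self) -> int:
        return sum(len(c.flagged) for c in self.columns)

    def column(self, phenotype_id: str) -> ColumnQC:
        for c in self.columns:
            if c.phenotype_id == phenotype_id:
                return c
        raise KeyError(phenotype_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phenotype_id": c.phenotype_id,
                    "median": c.median,
                    "lower_mad": c.lower_mad,
                    "upper_mad": c.upper_mad,
                    "n_flagged": len(c.flagged),
                    "n_valid": c.n_valid,
                    "kept": c.kept,
                }
                for c in self.columns
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "min_valid": self.min_valid,
            "columns": [
                {
                    "phenotype_id": c.phenotype_id,
                    "median": c.median,
                    "lower_mad": None if math.isnan(c.lower_mad) else c.lower_mad,
                    "upper_mad": None if math.isnan(c.upper_mad) else c.upper_mad,
                    "flagged": [[g, v] for g, v in c.flagged],
                    "n_valid": c.n_valid,
                    "kept": c.kept,
                }
                for c in self.columns
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def filter_metabolites(
    matrix: pd.DataFrame,
    k: float = DEFAULT_K,
    min_valid: int = DEFAULT_MIN_VALID,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Flag outliers per metabolite column and drop under-represented columns.

    ``matrix``: genotypes in rows, metabolites in columns, nonnegative
    intensities, NaN for missing. Flagged values are set to missing; a
    column is dropped iff its count of non-zero, non-missing, non-flagged
    values is below ``min_valid`` (a count of exactly ``min_valid`` keeps
    the column). Zero intensities enter the median but count as "zero" for
    the validity rule regardless of flagging.
    """
    if (matrix.fillna(0.0) < 0).any().any():
        raise DataError("phenotype matrix contains negative intensities")
    report = OutlierReport(k=k, min_valid=min_valid)
    filtered = matrix.copy().astype(float)
    keep: list[str] = []
    for col in matrix.columns:
        values = matrix[col].astype(float)
        if values.isna().all():
            report.columns.append(
                ColumnQC(str(col), math.nan, math.nan, math.nan, [], 0, False)
            )
            continue
        med, lmad, umad = asymmetric_mad(values.to_numpy())
        mask = flag_outliers(values.to_numpy(), k=k)
        flagged = [
            (str(g), float(v))
            for g, v, m in zip(matrix.index, values.to_numpy(), mask)
            if m
        ]
        filtered.loc[mask, col] = np.nan
        valid = values.notna().to_numpy() & (values.to_numpy() != 0.0) & ~mask
        n_valid = int(valid.sum())
        kept = n_valid >= min_valid
        report.columns.append(
            ColumnQC(str(col), med, lmad, umad, flagged, n_valid, kept)
        )
        if kept:
            keep.append(col)
    return filtered[keep], report


def read_phenotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV phenotype matrix (genotype rows, metabolite columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")
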