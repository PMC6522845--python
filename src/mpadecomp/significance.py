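"""FDR-controlled selection of significant SNP-phenotype associations.

Three selection modes over raw GWAS p-values:

* ``hierarchical`` (default): a two-stage family screen. Tests are grouped
  into families by phenotype; each family is summarized by its Simes
  combined p-value; Benjamini-Hochberg step-up at ``q1`` (default 0.1)
  selects families; within each selected family the
  Gavrilov-Benjamini-Sarkar (GBS) adaptive step-down procedure at ``q2``
  (default 7.9e-06) selects individual tests.
* ``flat``: GBS at ``q2`` pooled over all tests, ignoring families.
* ``fixed``: a plain p <= threshold cut.

The GBS critical values are ``c_i = i*q / (m + 1 - i*(1 - q))`` for
``i = 1..m``; the step-down rule rejects the largest prefix of the sorted
p-values that satisfies ``p_(i) <= c_i`` for every i up to the prefix end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .ingest import AssociationRecord

DEFAULT_Q1 = 0.1
DEFAULT_Q2 = 7.9e-06


def _check_pvalues(p: np.ndarray) -> None:
    if p.size == 0:
        raise DataError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")


def bh_stepup(p_values: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    Rejects the ``k*`` smallest p-values where ``k* = max{k : p_(k) <=
    k*q/m}``; ties are broken by rejecting every test with ``p <= p_(k*)``.
    """
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if not (0.0 < q < 1.0):
        raise ConfigError(f"q must be in (0, 1), got {q}")
    m = p.size
    order = np.sort(p)
    thresholds = np.arange(1, m + 1) * q / m
    passing = np.nonzero(order <= thresholds)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    cutoff = order[passing[-1]]
    return p <= cutoff


def gbs_critical_values(m: int, q: float) -> np.ndarray:
    """GBS step-down critical values ``c_i = i*q / (m + 1 - i*(1-q))``."""
    i = np.arange(1, m + 1, dtype=float)
    return i * q / (m + 1 - i * (1.0 - q))


def gbs_stepdown(p_values: Sequence[float], q: float) -> np.ndarray:
    """Gavrilov-Benjamini-Sarkar adaptive step-down rejection mask."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    if not (0.0 < q < 1.0):
        raise ConfigError(f"q must be in (0, 1), got {q}")
    m = p.size
    order = np.sort(p)
    crit = gbs_critical_values(m, q)
    ok = order <= crit
    if not ok[0]:
        return np.zeros(m, dtype=bool)
    # largest prefix with every sorted p under its critical value
    failures = np.nonzero(~ok)[0]
    k_star = int(failures[0]) if failures.size else m
    cutoff = order[k_star - 1]
    return p <= cutoff


def simes_pvalue(p_values: Sequence[float]) -> float:
    """Simes combined p-value: ``min_i m * p_(i) / i``, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    _check_pvalues(p)
    m = p.size
    order = np.sort(p)
    return float(min(1.0, np.min(m * order / np.arange(1, m + 1))))


@dataclass
class SignificanceResult:
    """Outcome of a significance filter run.

    ``table`` carries one row per input test with ``family_selected`` and
    ``significant`` stage annotations; ``records`` holds the significant
    :class:`AssociationRecord` objects.
    """

    table: pd.DataFrame
    mode: str
    q1: float | None
    q2: float | None
    threshold: float | None = None

    @property
    def records(self) -> list[AssociationRecord]:
        hits = self.table[self.table["significant"]]
        return [
            AssociationRecord(
                snp_id=row.snp_id,
                chrom=row.chrom,
                pos=int(row.pos),
                phenotype_id=row.phenotype_id,
                p_value=float(row.p_value),
                beta=float(row.beta),
            )
            for row in hits.itertuples()
        ]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def metadata(self) -> dict:
        return {
            "mode": self.mode,
            "q1": self.q1,
            "q2": self.q2,
            "threshold": self.threshold,
            "n_tests": int(len(self.table)),
            "n_significant": self.n_significant,
        }


def _records_frame(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    rows = [
        (r.snp_id, r.chrom, r.pos, r.phenotype_id, r.p_value, r.beta)
        for r in records
    ]
    frame = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "phenotype_id", "p_value", "beta"]
    )
    if frame.empty:
        raise DataError("no association records supplied")
    return frame


def hierarchical_filter(
    records: Iterable[AssociationRecord],
    q1: float = DEFAULT_Q1,
    q2: float | None = DEFAULT_Q2,
    mode: str = "hierarchical",
    threshold: float | None = None,
) -> SignificanceResult:
    """Select significant associations from raw p-values.

    Families are the phenotypes. See the module docstring for the three
    modes. Returns every input test annotated with the family-stage and
    test-stage decisions.
    """
    frame = _records_frame(records)
    frame["family_selected"] = False
    frame["significant"] = False

    if mode == "fixed":
        if threshold is None:
            raise ConfigError("fixed mode requires an explicit threshold")
        frame["significant"] = frame["p_value"] <= threshold
        frame["family_selected"] = frame["significant"]
        return SignificanceResult(frame, mode, None, None, threshold)

    if q2 is None:
        raise ConfigError(f"{mode} mode requires q2")

    if mode == "flat":
        mask = gbs_stepdown(frame["p_value"].to_numpy(), q2)
        frame["significant"] = mask
        frame["family_selected"] = mask
        return SignificanceResult(frame, mode, None, q2)

    if mode != "hierarchical":
        raise ConfigError(f"unknown significance mode {mode!r}")

    families = sorted(frame["phenotype_id"].unique())
    simes = np.array(
        [
            simes_pvalue(frame.loc[frame["phenotype_id"] == fam, "p_value"])
            for fam in families
        ]
    )
    selected = bh_stepup(simes, q1)
    selected_fams = {fam for fam, sel in zip(families, selected) if sel}
    frame["family_selected"] = frame["phenotype_id"].isin(selected_fams)
    for fam in selected_fams:
        idx = frame.index[frame["phenotype_id"] == fam]
        mask = gbs_stepdown(frame.loc[idx, "p_value"].to_numpy(), q2)
        frame.loc[idx[mask], "significant"] = True
    return SignificanceResult(frame, mode, q1, q2)
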