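"""Observer-agreement statistics for CNFL readings.

Given a complete images x readers table of CNFL values (expert readers and
the automated method alike), this module computes pairwise coefficients of
determination, intraclass correlation coefficients from two-way ANOVA,
Bland-Altman limits of agreement with the reproducibility coefficient
(RPC = 1.96 x SD of paired differences), and Hinkle's verbal correlation
bands.

The ICC variant is two-way random effects, absolute agreement, single
measures — ICC(2,1) — the standard choice for method comparison, where a
systematic offset between observers should count against agreement. The
consistency variant ICC(3,1) is available via ``variant="consistency"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReaderMatrix",
    "BlandAltman",
    "AgreementReport",
    "coefficient_of_determination",
    "icc_two_way",
    "bland_altman",
    "hinkle_band",
    "build_agreement_report",
]


@dataclass
class ReaderMatrix:
    """Complete images x readers table of CNFL values."""

    values: np.ndarray
    reader_ids: list[str]
    image_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D images x readers table")
        n, k = self.values.shape
        if k < 2:
            raise ValueError("need at least 2 readers")
        if n < 3:
            raise ValueError("need at least 3 images")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table has missing or non-finite cells")
        if len(self.reader_ids) != k or len(self.image_ids) != n:
            raise ValueError("id lists must match table dimensions")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.image_ids, columns=self.reader_ids)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    rpc: float
    loa_low: float
    loa_high: float


@dataclass
class AgreementReport:
    reader_ids: list[str]
    pairwise_r2: pd.DataFrame
    pairwise_icc: pd.DataFrame
    overall_icc: float
    bland_altman: dict[tuple[str, str], BlandAltman]
    hinkle_labels: pd.DataFrame = field(default=None)


def coefficient_of_determination(x, y) -> float:
    """Squared Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _icc_from_table(values: np.ndarray, variant: str) -> float:
    """ICC from two-way ANOVA mean squares on an n x k table."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "absolute_agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif variant == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        # all cells identical: perfect agreement by convention
        return 1.0
    return float((msr - mse) / denom)


def icc_two_way(
    matrix: ReaderMatrix, variant: str = "absolute_agreement"
) -> tuple[float, pd.DataFrame]:
    """Overall and pairwise ICCs of a complete reader matrix.

    Returns ``(overall_icc, pairwise_table)`` where the pairwise table holds
    the ICC of each two-reader submatrix (symmetric, unit diagonal).
    """
    overall = _icc_from_table(matrix.values, variant)
    k = len(matrix.reader_ids)
    table = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            table[i, j] = table[j, i] = _icc_from_table(
                matrix.values[:, [i, j]], variant
            )
    return overall, pd.DataFrame(table, index=matrix.reader_ids, columns=matrix.reader_ids)


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman summary of paired differences ``d = x - y``.

    The reproducibility coefficient is RPC = 1.96 x SD(d) with the sample
    standard deviation (n - 1); the limits of agreement are mean(d) +/- RPC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    rpc = 1.96 * sd_diff
    return BlandAltman(mean_diff, sd_diff, rpc, mean_diff - rpc, mean_diff + rpc)


def hinkle_band(r: float) -> str:
    """Hinkle's verbal band for a correlation in [0, 1].

    very_high for r >= 0.9, high for 0.7 <= r < 0.9, moderate for
    0.5 <= r < 0.7, low below 0.5.
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"correlation must lie in [0, 1], got {r}")
    if r >= 0.9:
        return "very_high"
    if r >= 0.7:
        return "high"
    if r >= 0.5:
        return "moderate"
    return "low"


def build_agreement_report(
    matrix: ReaderMatrix, variant: str = "absolute_agreement"
) -> AgreementReport:
    """All pairwise statistics plus the overall ICC for a reader matrix."""
    k = len(matrix.reader_ids)
    r2 = np.ones((k, k))
    labels = np.empty((k, k), dtype=object)
    ba: dict[tuple[str, str], BlandAltman] = {}
    for i in range(k):
        labels[i, i] = "very_high"
        for j in range(i + 1, k):
            r2[i, j] = r2[j, i] = coefficient_of_determination(
                matrix.values[:, i], matrix.values[:, j]
            )
            r = float(np.sqrt(r2[i, j]))
            corr = np.corrcoef(matrix.values[:, i], matrix.values[:, j])[0, 1]
            labels[i, j] = labels[j, i] = (
                hinkle_band(r) if corr >= 0 else "low"
            )
            ba[(matrix.reader_ids[i], matrix.reader_ids[j])] = bland_altman(
                matrix.values[:, i], matrix.values[:, j]
            )
    overall, pairwise_icc = icc_two_way(matrix, variant)
    ids = matrix.reader_ids
    return AgreementReport(
        reader_ids=list(ids),
        pairwise_r2=pd.DataFrame(r2, index=ids, columns=ids),
        pairwise_icc=pairwise_icc,
        overall_icc=overall,
        bland_altman=ba,
        hinkle_labels=pd.DataFrame(labels, index=ids, columns=ids),
    )
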