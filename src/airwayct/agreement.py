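"""Method-agreement and group-comparison statistics.

Everything needed to validate a new densitometric method against a manual
reference and to compare sensitized with control animals: Bland–Altman
agreement with ±2 SD limits, Pearson and intraclass correlation,
Spearman rank correlation, and the two-sided Mann–Whitney–Wilcoxon
rank-sum test.

Notes on conventions:

* Limits of agreement use exactly ±2 sample standard deviations of the
  paired differences (not ±1.96 SD).
* "Measurement error" is reported as the SD of the between-method
  differences; the report labels the field explicitly because the term has
  no single standard definition.
* The ICC is ICC(2,1): two-way random effects, absolute agreement, single
  measurement — the standard choice for two-method agreement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "bland_altman",
    "pearson",
    "icc",
    "spearman",
    "mann_whitney",
]

logger = logging.getLogger("airwayct")


@dataclass
class PairedMeasurements:
    """Two same-quantity measurement series over the same subjects (HU)."""

    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.ndim != 1 or self.method_b.ndim != 1:
            raise ValueError("paired measurements must be 1D sequences")
        if len(self.method_a) != len(self.method_b):
            raise ValueError(
                f"unequal lengths: {len(self.method_a)} vs {len(self.method_b)}"
            )
        if len(self.method_a) < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def n(self) -> int:
        return len(self.method_a)


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman bias and limits plus correlation indices for two methods."""

    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    pearson_r: float
    icc: float
    n: int
    #: SD of between-method differences, reported under the name used when
    #: quoting a single-scalar "measurement error"; interpretation, not a
    #: standard definition.
    measurement_error: float

    #: (mean, difference) pairs for the Bland–Altman plot.
    means: tuple = ()
    differences: tuple = ()

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "limits_of_agreement": [self.lower_limit, self.upper_limit],
            "limits_definition": "mean difference +/- 2 SD",
            "pearson_r": self.pearson_r,
            "icc_2_1": self.icc,
            "measurement_error": self.measurement_error,
            "measurement_error_definition": "SD of between-method differences",
        }


def bland_altman(pairs: PairedMeasurements) -> AgreementReport:
    """Bland–Altman agreement analysis of two measurement methods.

    Differences are ``a − b``; the bias is their mean, the limits of
    agreement are the bias ±2 sample SD (n−1 denominator).  Pearson r and
    ICC(2,1) for the same pairs are included in the report.
    """
    a, b = pairs.method_a, pairs.method_b
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    try:
        r = pearson(pairs)
    except ValueError:
        r = float("nan")
    return AgreementReport(
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        lower_limit=mean_diff - 2.0 * sd_diff,
        upper_limit=mean_diff + 2.0 * sd_diff,
        pearson_r=r,
        icc=icc(pairs) if pairs.n >= 3 else float("nan"),
        n=pairs.n,
        measurement_error=sd_diff,
        means=tuple((a + b) / 2.0),
        differences=tuple(diff),
    )


def pearson(pairs: PairedMeasurements) -> float:
    """Product-moment correlation between the two methods."""
    a, b = pairs.method_a, pairs.method_b
    if pairs.n < 3:
        raise ValueError("pearson requires n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    return float(stats.pearsonr(a, b).statistic)


def icc(pairs: PairedMeasurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the two-way mean squares with n subjects and k = 2 raters:

        ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE) / n)

    where MSR, MSC, MSE are the subject, rater and residual mean squares.
    Degenerate input (all values identical) returns 1 by convention.
    """
    if pairs.n < 3:
        raise ValueError("icc requires n >= 3")
    y = np.column_stack([pairs.method_a, pairs.method_b])  # n x k
    n, k = y.shape
    if np.ptp(y) == 0:
        logger.info("icc: all values identical; returning 1 by convention")
        return 1.0
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        logger.info("icc: zero denominator on degenerate input; returning 1")
        return 1.0
    return float((msr - mse) / denom)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Returns ``(rho, p)``; the p-value comes from the large-sample t
    approximation.  Requires n ≥ 4 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("spearman requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney–Wilcoxon rank-sum test.

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of ``group_a``.
    The p-value is exact (null-distribution enumeration) when
    ``n_a * n_b <= 400`` and there are no ties across the pooled sample;
    otherwise the normal approximation with tie and continuity correction
    is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)
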