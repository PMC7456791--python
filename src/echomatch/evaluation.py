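"""Error metrics and the statistical battery for match evaluation.

Every match method is scored against the landmark gold standard. The error
of one match is the signed per-axis difference ``E = match - gold`` in mm
on (LR, AP, SI). Summaries report signed mean/SD/range plus the median and
interquartile range of ``|E|`` (quartiles by linear interpolation between
order statistics). Method comparisons use the field's nonparametric
location and dispersion tests (Mann-Whitney U, Ansari-Bradley), Pearson
correlation with the gold standard, paired t-tests and the Pitman-Morgan
paired variance test, and interobserver variation (IOV) quantified per
fraction as the maximum difference between observers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .grids import AXIS_NAMES, Displacement3D

__all__ = [
    "ErrorRecord",
    "SummaryStats",
    "TestResult",
    "NormalityResult",
    "match_error",
    "summarize_errors",
    "errors_table",
    "euclidean_error_stats",
    "correlation_with_gold",
    "mann_whitney_u",
    "ansari_bradley",
    "paired_tests",
    "pitman_morgan",
    "iov",
    "normality_check",
]

EXACT_CROSSOVER = 12  # pooled size at or below which rank tests are exact


@dataclass(frozen=True)
class ErrorRecord:
    """Signed per-axis error of one match versus the gold standard."""

    patient_id: int
    fraction: int
    method: str
    e_mm: Tuple[float, float, float]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.e_mm, dtype=float)


@dataclass
class SummaryStats:
    """Per-axis error summary: signed stats plus absolute-error median/IQR."""

    emean: np.ndarray
    estd: np.ndarray  # nan when n < 2
    emin: np.ndarray
    emax: np.ndarray
    emed: np.ndarray  # median of |E|
    eiqr: np.ndarray  # IQR of |E|
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Emean": self.emean,
                "Estd": self.estd,
                "Emin": self.emin,
                "Emax": self.emax,
                "Emed": self.emed,
                "EIQR": self.eiqr,
            },
            index=list(AXIS_NAMES),
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: Optional[bool]  # None when the test is undefined


def match_error(
    result: Displacement3D,
    gold: Displacement3D,
    patient_id: int = 0,
    fraction: int = 0,
    method: str = "",
) -> ErrorRecord:
    """E = match result - gold standard, per axis."""
    e = result.as_array() - gold.as_array()
    return ErrorRecord(patient_id, fraction, method, tuple(e))


def errors_table(records: Sequence[ErrorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "fraction": [r.fraction for r in records],
            "method": [r.method for r in records],
            "e_lr_mm": [r.e_mm[0] for r in records],
            "e_ap_mm": [r.e_mm[1] for r in records],
            "e_si_mm": [r.e_mm[2] for r in records],
        }
    )


def summarize_errors(records: Sequence[ErrorRecord]) -> SummaryStats:
    """Signed mean/SD/min/max and |E| median/IQR per axis."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty error list")
    e = np.stack([r.as_array() for r in records])
    a = np.abs(e)
    estd = e.std(axis=0, ddof=1) if len(records) >= 2 else np.full(3, np.nan)
    return SummaryStats(
        emean=e.mean(axis=0),
        estd=estd,
        emin=e.min(axis=0),
        emax=e.max(axis=0),
        emed=np.median(a, axis=0),
        eiqr=np.percentile(a, 75, axis=0) - np.percentile(a, 25, axis=0),
        n=len(records),
    )


def euclidean_error_stats(records: Sequence[ErrorRecord]) -> Tuple[float, float]:
    """Mean and sample SD of the per-record Euclidean error norm."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty error list")
    norms = np.linalg.norm(np.stack([r.as_array() for r in records]), axis=1)
    sd = float(norms.std(ddof=1)) if len(norms) >= 2 else np.nan
    return float(norms.mean()), sd


def correlation_with_gold(
    method_shifts: np.ndarray, gold_shifts: np.ndarray, spearman: bool = False
) -> pd.DataFrame:
    """Per-axis correlation coefficient C (Pearson by default) with p-values."""
    m = np.atleast_2d(np.asarray(method_shifts, dtype=float))
    g = np.atleast_2d(np.asarray(gold_shifts, dtype=float))
    if m.shape != g.shape or m.shape[1] != 3:
        raise ValueError("method and gold shift arrays must both be (n, 3)")
    if m.shape[0] < 3:
        raise ValueError("correlation requires at least 3 paired shifts")
    rows = []
    for ax in range(3):
        x, y = m[:, ax], g[:, ax]
        if x.std() == 0 or y.std() == 0:
            rows.append({"axis": AXIS_NAMES[ax], "C": np.nan, "p": np.nan})
            continue
        if spearman:
            r, p = stats.spearmanr(x, y)
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"axis": AXIS_NAMES[ax], "C": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("axis")


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for a location difference.

    U counts pairs with x > y plus half the ties. The p-value is exact (by
    enumeration of the permutation null) for small tie-free samples and a
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if np.all(np.concatenate([x, y]) == x.flat[0]):
        # every observation identical: no evidence either way
        return TestResult(len(x) * len(y) / 2.0, 1.0, "mann-whitney-u", False)
    exact = (len(x) + len(y) <= EXACT_CROSSOVER) and not _has_ties(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "mann-whitney-u", exact)


def ansari_bradley(x, y) -> TestResult:
    """Two-sided Ansari-Bradley test for a dispersion difference.

    The statistic sums, over x, ranks assigned from both ends of the pooled
    ordering inward; small tie-free samples use the exact null distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    exact = not _has_ties(x, y) and max(len(x), len(y)) < 55
    res = stats.ansari(x, y)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "ansari-bradley", exact)


def pitman_morgan(a, b) -> TestResult:
    """Pitman-Morgan paired variance test.

    For paired samples, var(A) = var(B) iff corr(A+B, A-B) = 0; the test
    statistic is t = r sqrt(n-2) / sqrt(1 - r^2) on n-2 df. Degenerate
    sums or differences (e.g. B = A + constant) give statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("paired variance test requires n >= 3")
    s, d = a + b, a - b
    if s.std() == 0 or d.std() == 0:
        return TestResult(0.0, 1.0, "pitman-morgan", False)
    r = float(np.corrcoef(s, d)[0, 1])
    if abs(r) >= 1.0:
        return TestResult(np.inf * np.sign(r), 0.0, "pitman-morgan", False)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return TestResult(float(t), float(min(p, 1.0)), "pitman-morgan", False)


def paired_tests(errors_a, errors_b) -> Tuple[TestResult, TestResult]:
    """Paired t-test (location) and Pitman-Morgan test (variance)."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("paired tests require n >= 3")
    if np.all(a == b) or np.std(a - b) == 0:
        t_res = TestResult(0.0, 1.0, "paired-t", False)
    else:
        t = stats.ttest_rel(a, b)
        t_res = TestResult(float(t.statistic), float(t.pvalue), "paired-t", False)
    return t_res, pitman_morgan(a, b)


def iov(observer_table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Interobserver variation per fraction plus its quantile table.

    Input: one row per (patient, fraction, observer) with displacement
    columns ``dx_lr_mm, dy_ap_mm, dz_si_mm``. IOV is, per fraction and
    axis, the maximum absolute pairwise difference between observers
    (equivalently max - min). The quantile table reports the 25/50/75%
    quantiles and IQR of IOV across fractions.
    """
    cols = ["dx_lr_mm", "dy_ap_mm", "dz_si_mm"]
    grouped = observer_table.groupby(["patient_id", "fraction"])
    if (grouped["observer_id"].nunique() < 2).any():
        raise ValueError("IOV requires at least two observers per fraction")
    per_fraction = (grouped[cols].max() - grouped[cols].min()).reset_index()
    per_fraction.columns = ["patient_id", "fraction", "iov_lr_mm", "iov_ap_mm",
                            "iov_si_mm"]
    qcols = ["iov_lr_mm", "iov_ap_mm", "iov_si_mm"]
    q = per_fraction[qcols].quantile([0.25, 0.5, 0.75])
    q.loc["IQR"] = q.loc[0.75] - q.loc[0.25]
    q.index = ["25%", "50%", "75%", "IQR"]
    return per_fraction, q


def normality_check(errors, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality check; ``normal`` is None when undefined."""
    e = np.asarray(errors, dtype=float)
    if len(e) < 8:
        return NormalityResult(np.nan, np.nan, None)
    if np.all(e == e[0]):
        return NormalityResult(np.nan, np.nan, None)
    w, p = stats.shapiro(e)
    return NormalityResult(float(w), float(p), bool(p >= alpha))
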