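"""Method-comparison and test–retest statistics.

Implements the study's statistical toolbox: signed and absolute test–retest
variability (TRV/aTRV), the one-way intraclass correlation coefficient
ICC = (BSMSS − WSMSS)/(BSMSS + WSMSS), percentage bias between methods
(both printed definitions), Pearson correlation, repeated-measures ANOVA
with Fisher's LSD follow-up, and the arteriovenous plasma difference at
fixed sampling timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BloodSampleTable

__all__ = [
    "PairedMeasurements",
    "trv",
    "atrv",
    "icc",
    "icc_classification",
    "percent_bias",
    "pearson_r",
    "rm_anova_lsd",
    "RmAnovaResult",
    "av_difference",
    "av_profile_summary",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Aligned test/retest values for one parameter, region and method."""

    subjects: tuple
    test: np.ndarray
    retest: np.ndarray
    parameter: str = "VT"
    region: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.test, dtype=float)
        r = np.asarray(self.retest, dtype=float)
        object.__setattr__(self, "test", t)
        object.__setattr__(self, "retest", r)
        if t.shape != r.shape or len(self.subjects) != t.size:
            raise ValueError("subjects, test and retest must be aligned and equal length")
        if t.size < 2:
            raise ValueError("need at least 2 subjects")


def trv(test, retest):
    """Signed test–retest variability (%): (retest − test)/(mean of the two)·100."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    mean = (test + retest) / 2.0
    if np.any(mean == 0):
        raise ZeroDivisionError("test/retest mean is zero")
    out = 100.0 * (retest - test) / mean
    return float(out) if out.ndim == 0 else out


def atrv(test, retest):
    """Absolute test–retest variability (%): |TRV|."""
    return np.abs(trv(test, retest))


def icc(pairs: PairedMeasurements) -> float:
    """One-way (subject-factor) intraclass correlation coefficient.

    ICC = (BSMSS − WSMSS)/(BSMSS + WSMSS) where BSMSS and WSMSS are the
    between- and within-subject mean sums of squares; ranges (−1, 1], with 1
    when retest reproduces test exactly.
    """
    data = np.column_stack([pairs.test, pairs.retest])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    bsmss = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    wsmss = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    return float((bsmss - wsmss) / (bsmss + wsmss))


def icc_classification(value: float) -> str:
    """Reliability band: moderate 0.50–0.75, good 0.75–0.90, excellent > 0.9."""
    if value > 0.9:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.50:
        return "moderate"
    return "poor"


def percent_bias(reference, alternative, definition: str = "vs_average"):
    """Mean percentage difference of an alternative method from the reference.

    ``vs_average``: per-pair 100·(alt − ref)/((alt + ref)/2) — the ratio of
    the V_T difference to the two methods' average; antisymmetric under
    swapping the roles.  ``vs_reference``: 100·(alt − ref)/ref, the relative
    difference from the reference estimate.  Returns the mean over pairs.
    """
    ref = np.atleast_1d(np.asarray(reference, dtype=float))
    alt = np.atleast_1d(np.asarray(alternative, dtype=float))
    if ref.shape != alt.shape:
        raise ValueError("reference and alternative must be aligned")
    if definition == "vs_average":
        denom = (ref + alt) / 2.0
    elif definition == "vs_reference":
        denom = ref
    else:
        raise ValueError("definition must be 'vs_average' or 'vs_reference'")
    if np.any(denom == 0):
        raise ZeroDivisionError("zero denominator in percent bias")
    return float(np.mean(100.0 * (alt - ref) / denom))


def pearson_r(x, y):
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RmAnovaResult:
    f_statistic: float
    df: tuple  # (df_method, df_error)
    p_value: float
    ms_error: float
    lsd: pd.DataFrame = field(default_factory=pd.DataFrame)
    omnibus_significant: bool = False


def rm_anova_lsd(table: pd.DataFrame, alpha: float = 0.05,
                 force_pairwise: bool = False) -> RmAnovaResult:
    """Repeated-measures ANOVA (subjects × methods) with Fisher's LSD.

    ``table``: complete subjects-by-methods values (rows = subjects).  The
    omnibus F tests the method effect against the subject×method residual;
    LSD pairwise t-tests (pooled MS_error, same df) are run only when the
    omnibus test is significant, unless ``force_pairwise``.
    """
    if table.isna().any().any():
        raise ValueError("missing cells: RM-ANOVA requires a complete table")
    data = table.to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 methods")
    grand = data.mean()
    method_means = data.mean(axis=0)
    subject_means = data.mean(axis=1)
    ss_method = n * np.sum((method_means - grand) ** 2)
    ss_subject = k * np.sum((subject_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_method - ss_subject
    df_method = k - 1
    df_error = (n - 1) * (k - 1)
    ms_method = ss_method / df_method
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f = 0.0 if ms_method == 0 else np.inf
        p = 1.0 if ms_method == 0 else 0.0
    else:
        f = ms_method / ms_error
        p = float(stats.f.sf(f, df_method, df_error))
    significant = p < alpha

    lsd_rows = []
    if (significant or force_pairwise) and ms_error > 0:
        se = np.sqrt(2.0 * ms_error / n)
        for i, j in combinations(range(k), 2):
            diff = method_means[i] - method_means[j]
            tstat = diff / se
            pij = 2.0 * float(stats.t.sf(abs(tstat), df_error))
            lsd_rows.append(
                {
                    "method_a": table.columns[i],
                    "method_b": table.columns[j],
                    "mean_difference": float(diff),
                    "t": float(tstat),
                    "p": pij,
                    "significant": pij < alpha,
                }
            )
    return RmAnovaResult(
        f_statistic=float(f),
        df=(df_method, df_error),
        p_value=float(p),
        ms_error=float(ms_error),
        lsd=pd.DataFrame(lsd_rows),
        omnibus_significant=bool(significant),
    )


def _parent_at(table: BloodSampleTable, timepoint: float) -> float:
    idx = np.flatnonzero(np.isclose(table.times, timepoint, atol=1e-6))
    if idx.size == 0:
        raise ValueError(f"timepoint {timepoint} min missing from {table.site} table")
    return float(table.parent_plasma[idx[0]])


def av_difference(
    arterial: BloodSampleTable,
    venous: BloodSampleTable,
    timepoints=(30.0, 60.0, 120.0, 180.0),
) -> pd.Series:
    """Arteriovenous plasma-parent difference, % of arterial, per timepoint.

    Positive when arterial exceeds venous (the convention under which the
    30-min difference is positive before the curves cross near 60 min).
    """
    out = {}
    for tp in timepoints:
        a = _parent_at(arterial, tp)
        v = _parent_at(venous, tp)
        if a == 0:
            raise ZeroDivisionError(f"zero arterial concentration at {tp} min")
        out[float(tp)] = 100.0 * (a - v) / a
    return pd.Series(out, name="av_difference_pct")


def av_profile_summary(pairs, timepoints=(30.0, 60.0, 120.0, 180.0)) -> pd.DataFrame:
    """Cohort mean ± SD of the A–V difference over (arterial, venous) pairs."""
    per_subject = [av_difference(a, v, timepoints) for a, v in pairs]
    mat = pd.DataFrame(per_subject)
    return pd.DataFrame(
        {
            "time_min": list(mat.columns),
            "mean_pct": mat.mean(axis=0).to_numpy(),
            "sd_pct": mat.std(axis=0, ddof=1).to_numpy(),
            "n": len(per_subject),
        }
    )
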