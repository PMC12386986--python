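"""Per-feature ADC-vs-SCC group comparison.

Each feature is summarised as median (Q1; Q3) per class.  Normality of
each group is assessed with the Shapiro–Wilk test at alpha = 0.05; if
both groups look normal the classes are compared with Welch's unequal-
variance t-test, otherwise with the two-sided Mann–Whitney U test
(exact enumeration for n <= 8 per group, normal approximation with tie
correction above).  No multiple-testing correction is applied by
default, matching the usual per-feature reporting; a Benjamini–Hochberg
option is available but note that with 93 features ~5% false positives
are expected under the null without it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_feature", "summarize_all"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    median_A: float
    q1_A: float
    q3_A: float
    median_B: float
    q1_B: float
    q3_B: float
    test_used: str  # "welch_t" | "mann_whitney"
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    q1, med, q3 = np.percentile(x, (25, 50, 75))
    return float(med), float(q1), float(q3)


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False  # Shapiro-Wilk undefined for constant data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue >= ALPHA


def compare_feature(
    values_A, values_B, feature: str = "", alpha: float = ALPHA
) -> GroupComparison:
    """Compare one feature between two groups (A = ADC, B = SCC)."""
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    med_a, q1_a, q3_a = _quartiles(a)
    med_b, q1_b, q3_b = _quartiles(b)

    const_a, const_b = np.ptp(a) == 0, np.ptp(b) == 0
    if const_a and const_b and a[0] == b[0]:
        # both groups one identical constant: no evidence of any difference
        return GroupComparison(feature, med_a, q1_a, q3_a, med_b, q1_b, q3_b,
                               "mann_whitney", 1.0)
    if const_a or const_b:
        warnings.warn(
            f"{feature or 'feature'}: constant group, Shapiro-Wilk undefined; "
            "using Mann-Whitney",
            stacklevel=2,
        )
        normal = False
    else:
        normal = _is_normal(a) and _is_normal(b)

    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
    else:
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney"
    return GroupComparison(
        feature, med_a, q1_a, q3_a, med_b, q1_b, q3_b, test, float(res.pvalue)
    )


def summarize_all(
    table: pd.DataFrame, labels, per_patient_groups=None
) -> tuple[list[GroupComparison], int]:
    """One GroupComparison per feature column (label 0 = group A = ADC).

    ``per_patient_groups`` (optional patient ids) collapses repeated
    images to their per-patient mean first, avoiding the independence
    assumption over repeated slices of the same patient.
    Returns (comparisons, significant_count).
    """
    labels = np.asarray(labels)
    if per_patient_groups is not None:
        df = table.copy()
        df["__label"] = labels
        df["__patient"] = np.asarray(per_patient_groups)
        df = df.groupby("__patient", sort=True).mean(numeric_only=True)
        labels = df.pop("__label").round().astype(int).to_numpy()
        table = df
    comparisons = [
        compare_feature(
            table.loc[labels == 0, col], table.loc[labels == 1, col], feature=col
        )
        for col in table.columns
    ]
    return comparisons, sum(c.significant for c in comparisons)


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabular report shaped like the usual radiomics group tables."""
    return pd.DataFrame(
        {
            "feature": [c.feature for c in comparisons],
            "ADC_median": [c.median_A for c in comparisons],
            "ADC_Q1": [c.q1_A for c in comparisons],
            "ADC_Q3": [c.q3_A for c in comparisons],
            "SCC_median": [c.median_B for c in comparisons],
            "SCC_Q1": [c.q1_B for c in comparisons],
            "SCC_Q3": [c.q3_B for c in comparisons],
            "test_used": [c.test_used for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
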