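"""Laterality indices, repeatability ICCs and the assay's hypothesis tests.

A fish's lateral preference is summarized by the left-right ratio
``right / (left + right)`` of a side-split measure (NOA or DIR): values
below 0.33 indicate a strong left preference, above 0.67 a strong right
preference, and the closed interval [0.33, 0.67] balanced behavior. The
bias index ``max(left, right) / (left + right)`` measures the strength of
lateralization regardless of direction (0.5 symmetric, 1.0 fully
one-sided). Repeatability across repeated assays is quantified with the
single-rater intraclass correlation; associations with superficial-neuromast
counts use Kendall's tau-b; paired before/after comparisons use the Wilcoxon
signed-rank test with Holm's step-down multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# ratios, bias indices, preference categories
# ---------------------------------------------------------------------------

def lr_ratio(left: float, right: float) -> float:
    """Right-side share of a side-split measure: right / (left + right).

    Returns NaN (undefined) when both sides are zero — such fish made no
    approaches and are excluded from preference histograms, never coerced
    to 0.5.
    """
    if left < 0 or right < 0:
        raise ValueError("left and right must be non-negative")
    total = left + right
    if total == 0:
        return math.nan
    return right / total


def bias_index(left: float, right: float) -> float:
    """Strength of lateralization: max(left, right) / (left + right).

    Equals ``max(r, 1 - r)`` for ``r = lr_ratio(left, right)``; in [0.5, 1]
    when defined, NaN when both sides are zero.
    """
    if left < 0 or right < 0:
        raise ValueError("left and right must be non-negative")
    total = left + right
    if total == 0:
        return math.nan
    return max(left, right) / total


def classify_preference(ratio: float) -> str:
    """Bin a left-right ratio: <0.33 left, [0.33, 0.67] balanced, >0.67 right."""
    if isinstance(ratio, float) and math.isnan(ratio):
        return "undefined"
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    if ratio < 0.33:
        return "left"
    if ratio > 0.67:
        return "right"
    return "balanced"


def laterality_record(
    noa_left: float,
    noa_right: float,
    dir_left_s: float,
    dir_right_s: float,
    fish_id: str | None = None,
    population: str | None = None,
    condition: str = "none",
) -> dict:
    """One fish x condition row of laterality indices and categories."""
    r_noa = lr_ratio(noa_left, noa_right)
    r_dir = lr_ratio(dir_left_s, dir_right_s)
    return {
        "fish_id": fish_id,
        "population": population,
        "condition": condition,
        "noa_left": noa_left,
        "noa_right": noa_right,
        "dir_left_s": dir_left_s,
        "dir_right_s": dir_right_s,
        "lr_noa_ratio": r_noa,
        "lr_dir_ratio": r_dir,
        "bias_index_noa": bias_index(noa_left, noa_right),
        "bias_index_dir": bias_index(dir_left_s, dir_right_s),
        "preference_noa": classify_preference(r_noa),
        "preference_dir": classify_preference(r_dir),
    }


# ---------------------------------------------------------------------------
# intraclass correlation (repeatability)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """Single-rater intraclass correlation from a subjects x repeats matrix.

    ``kappa`` is the consistency ICC, identically ``(F - 1)/(F + k - 1)``
    for ``F = MSR/MSE``; ``kappa_absolute`` is the absolute-agreement
    (two-way random raters) variant, which additionally penalizes a
    systematic shift between repeats. ``p_value`` is the F-test of the
    between-subject mean square against residual, df1 = n - 1,
    df2 = (n - 1)(k - 1).
    """

    kappa: float
    kappa_absolute: float
    F: float
    df1: int
    df2: int
    p_value: float
    label: str
    n_subjects: int
    n_repeats: int


def interpret_kappa(kappa: float) -> str:
    """Agreement label for an ICC: none / fair / moderate / substantial /
    almost perfect, with bin edges 0.2, 0.4, 0.6 and 0.8."""
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.2:
        return "none"
    if kappa < 0.4:
        return "fair"
    if kappa < 0.6:
        return "moderate"
    if kappa < 0.8:
        return "substantial"
    return "almost perfect"


def icc_from_f(F: float, k: int) -> float:
    """Consistency ICC from its F statistic: (F - 1) / (F + k - 1).

    Negative values (F < 1, i.e. less between-subject than residual
    variance) are reported as 0, the convention used when printing kappas.
    """
    if F <= 0:
        raise ValueError("F must be positive")
    if k < 2:
        raise ValueError("k must be at least 2")
    return max(0.0, (F - 1.0) / (F + k - 1.0))


def icc_repeatability(matrix: np.ndarray | pd.DataFrame) -> ICCResult:
    """Two-way single-rater ICC from a complete subjects x repeats matrix.

    The mean-squares decomposition of the two-way layout gives the
    between-subject (MSR), between-repeat (MSC) and residual (MSE) mean
    squares; the consistency ICC is (MSR - MSE)/(MSR + (k-1) MSE) and the
    absolute-agreement ICC adds the repeat-effect term k (MSC - MSE)/n to
    the denominator. Missing cells are rejected — no imputation.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x repeats)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 repeats")
    if np.isnan(m).any():
        raise ValueError("matrix has missing cells; ICC requires a complete "
                         "design (no imputation is performed)")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    df2 = (n - 1) * (k - 1)
    mse = np.sum(resid**2) / df2

    if mse == 0.0:
        f_stat = math.inf
        kappa_c = 1.0 if msr > 0 else 0.0
        kappa_a = kappa_c
        p = 0.0 if msr > 0 else 1.0
    else:
        f_stat = msr / mse
        kappa_c = (msr - mse) / (msr + (k - 1) * mse)
        kappa_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        p = float(stats.f.sf(f_stat, n - 1, df2))

    return ICCResult(
        kappa=float(kappa_c),
        kappa_absolute=float(kappa_a),
        F=float(f_stat),
        df1=n - 1,
        df2=df2,
        p_value=p,
        label=interpret_kappa(max(0.0, float(kappa_c))),
        n_subjects=n,
        n_repeats=k,
    )


# ---------------------------------------------------------------------------
# rank correlation, fasting deltas, paired tests
# ---------------------------------------------------------------------------

def kendall_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    The p-value is exact (permutation null) for small untied samples and
    uses the tie-corrected normal approximation otherwise. A constant
    vector leaves tau undefined: (nan, nan) is returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


def fasting_delta(
    records_before: pd.DataFrame,
    records_after: pd.DataFrame,
    measures: Sequence[str] = ("noa_total", "dir_total_s"),
    on: str = "fish_id",
) -> pd.DataFrame:
    """Per-fish after-minus-before differences of the given measures.

    Both tables must cover exactly the same fish; unmatched ids raise with
    the offending ids listed. The result has one row per fish with columns
    ``delta_<measure>`` and can be joined to a sensory profile table for
    correlation analyses.
    """
    before_ids = set(records_before[on])
    after_ids = set(records_after[on])
    if before_ids != after_ids:
        only_b = sorted(before_ids - after_ids)
        only_a = sorted(after_ids - before_ids)
        raise ValueError(
            f"unmatched fish ids: only-before={only_b}, only-after={only_a}"
        )
    b = records_before.set_index(on)
    a = records_after.set_index(on)
    out = pd.DataFrame(index=b.index.sort_values())
    for meas in measures:
        out[f"delta_{meas}"] = a[meas] - b[meas]
    return out.reset_index()


def paired_wilcoxon_holm(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> pd.DataFrame:
    """Wilcoxon signed-rank tests over a declared family, Holm-adjusted.

    ``pairs`` maps a test name to its (before, after) matched vectors. Tests
    whose differences are all zero are undefined (statistic and p reported
    as NaN, noted) and excluded from the Holm family. Returns a long-format
    table with the signed-rank statistic V, raw and adjusted p.
    """
    rows = []
    for name, (before, after) in pairs.items():
        before = np.asarray(before, float)
        after = np.asarray(after, float)
        if before.shape != after.shape or before.size == 0:
            raise ValueError(f"test {name!r}: before/after must be matched "
                             "non-empty vectors")
        diffs = after - before
        if np.all(diffs == 0):
            rows.append({"test": name, "V": math.nan, "p_raw": math.nan,
                         "note": "all differences zero; test undefined"})
        else:
            res = stats.wilcoxon(after, before)
            rows.append({"test": name, "V": float(res.statistic),
                         "p_raw": float(res.pvalue), "note": ""})
    table = pd.DataFrame(rows)
    table["p_holm"] = math.nan
    defined = table["p_raw"].notna()
    if defined.any():
        adj = multipletests(table.loc[defined, "p_raw"], method="holm")[1]
        table.loc[defined, "p_holm"] = adj
    return table
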