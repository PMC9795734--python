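import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vabtrack import (
    bias_index,
    classify_preference,
    fasting_delta,
    icc_from_f,
    icc_repeatability,
    interpret_kappa,
    kendall_correlation,
    laterality_record,
    lr_ratio,
    paired_wilcoxon_holm,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def kendall_tau_b_oracle(x, y):
    """Tau-b by O(n^2) enumeration of all pairs, with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tie_x) * (n0 - tie_y))
    return (conc - disc) / denom if denom else math.nan


def kendall_exact_p_oracle(x, y):
    """Two-sided exact p for untied samples from the permutation null.

    The number of permutations of 0..n-1 with a given count of concordant
    pairs follows the inversion-count (Mahonian) recursion, which is the
    exact null distribution of tau.
    """
    n = len(x)
    counts = np.array([1.0])
    for m in range(2, n + 1):  # convolve with a length-m uniform block
        counts = np.convolve(counts, np.ones(m))
    n0 = n * (n - 1) // 2
    # observed discordant-pair count
    xo = np.argsort(x)
    y_ord = np.asarray(y)[xo]
    disc = sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if y_ord[i] > y_ord[j]
    )
    stat = abs(n0 - 2 * disc)  # |concordant - discordant|
    d_vals = np.arange(len(counts))
    keep = np.abs(n0 - 2 * d_vals) >= stat
    return counts[keep].sum() / counts.sum()


# ---------------------------------------------------------------------------
# ratios and categories
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "left, right, ratio, bias",
    [
        (5, 5, 0.5, 0.5),
        (10, 0, 0.0, 1.0),
        (0, 7, 1.0, 1.0),
        (3, 3, 0.5, 0.5),
        (1, 3, 0.75, 0.75),
    ],
)
def test_ratio_and_bias_arithmetic(left, right, ratio, bias):
    assert lr_ratio(left, right) == pytest.approx(ratio)
    assert bias_index(left, right) == pytest.approx(bias)


def test_zero_zero_is_undefined_not_half():
    assert math.isnan(lr_ratio(0, 0))
    assert math.isnan(bias_index(0, 0))
    assert classify_preference(lr_ratio(0, 0)) == "undefined"
    with pytest.raises(ValueError):
        lr_ratio(-1, 2)


@pytest.mark.parametrize(
    "ratio, label",
    [
        (0.2, "left"),
        (0.5, "balanced"),
        (0.33, "balanced"),   # boundaries are inside the balanced interval
        (0.67, "balanced"),
        (0.329999, "left"),
        (0.670001, "right"),
        (0.8, "right"),
    ],
)
def test_preference_bins(ratio, label):
    assert classify_preference(ratio) == label


@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
)
@settings(deadline=None)
def test_bias_index_identity(left, right):
    """bias_index == max(r, 1 - r) wherever the ratio is defined."""
    r = lr_ratio(left, right)
    b = bias_index(left, right)
    if left + right == 0:
        assert math.isnan(r) and math.isnan(b)
    else:
        assert b == pytest.approx(max(r, 1 - r))
        assert 0.5 <= b <= 1.0


def test_laterality_record_fields():
    rec = laterality_record(2, 6, 1.0, 3.0, fish_id="f1", population="tinaja")
    assert rec["lr_noa_ratio"] == pytest.approx(0.75)
    assert rec["preference_noa"] == "right"
    assert rec["bias_index_dir"] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_mean_squares_oracle(m):
    """Brute-force two-way ANOVA decomposition (loops, no vectorization)."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    ssr = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def test_icc_agrees_with_mean_squares_oracle(rng):
    m = rng.normal(size=(6, 3))
    res = icc_repeatability(m)
    assert res.kappa == pytest.approx(icc_mean_squares_oracle(m), abs=1e-10)


def test_icc_agrees_with_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    m = rng.normal(loc=rng.normal(0, 2, size=(7, 1)), scale=1.0, size=(7, 3))
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(7), 3),
        "rater": np.tile(np.arange(3), 7),
        "score": m.ravel(),
    })
    table = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                     ratings="score").set_index("Type")
    res = icc_repeatability(m)
    assert res.kappa == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
    assert res.kappa_absolute == pytest.approx(table.loc["ICC(A,1)", "ICC"],
                                               abs=1e-9)
    assert res.F == pytest.approx(table.loc["ICC(C,1)", "F"], abs=1e-9)
    assert res.p_value == pytest.approx(table.loc["ICC(C,1)", "pval"], abs=1e-9)


def test_perfect_repeatability():
    m = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 3))
    res = icc_repeatability(m)
    assert res.kappa == pytest.approx(1.0)
    assert res.p_value == 0.0
    assert res.label == "almost perfect"


def test_icc_near_zero_under_the_null(rng):
    # repeats shuffled independently per subject: no subject effect survives
    m = rng.normal(size=(300, 3))
    res = icc_repeatability(m)
    assert abs(res.kappa) < 0.1
    assert res.label == "none"


def test_icc_rejects_missing_cells_and_degenerate_shapes():
    with pytest.raises(ValueError, match="missing"):
        icc_repeatability([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError):
        icc_repeatability([[1.0, 2.0]])


@pytest.mark.parametrize(
    "F, k, expected",
    [(4.5, 3, 0.54), (2.4, 3, 0.32), (1.0, 3, 0.0)],
)
def test_icc_from_f_published_values(F, k, expected):
    assert icc_from_f(F, k) == pytest.approx(expected, abs=0.005)


def test_icc_from_f_monotone_and_limits():
    fs = np.linspace(0.5, 50, 200)
    vals = [icc_from_f(f, 3) for f in fs]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert icc_from_f(1e9, 3) == pytest.approx(1.0, abs=1e-8)
    assert icc_from_f(0.2, 3) == 0.0  # clipped below


@pytest.mark.parametrize(
    "kappa, label",
    [(0.54, "moderate"), (0.085, "none"), (0.39, "fair"), (0.32, "fair"),
     (0.0, "none"), (0.7, "substantial"), (0.95, "almost perfect")],
)
def test_kappa_interpretation_bins(kappa, label):
    assert interpret_kappa(kappa) == label


@given(st.floats(min_value=0.01, max_value=100.0))
@settings(deadline=None)
def test_icc_from_f_range(F):
    v = icc_from_f(F, 3)
    assert 0.0 <= v < 1.0


def test_icc_consistency_identity_on_random_matrices(rng):
    for _ in range(20):
        m = rng.normal(size=(5, 4))
        res = icc_repeatability(m)
        assert icc_from_f(res.F, 4) == pytest.approx(max(0.0, res.kappa),
                                                     abs=1e-9)


# ---------------------------------------------------------------------------
# Kendall, fasting deltas, paired tests
# ---------------------------------------------------------------------------

def test_kendall_trivial_cases():
    tau, _ = kendall_correlation([1, 2, 3], [2, 4, 6])
    assert tau == pytest.approx(1.0)
    tau, _ = kendall_correlation([1, 2, 3], [3, 2, 1])
    assert tau == pytest.approx(-1.0)
    tau, p = kendall_correlation([1, 1, 1], [1, 2, 3])
    assert math.isnan(tau) and math.isnan(p)


def test_kendall_matches_pair_counting_oracle(rng):
    for _ in range(100):
        n = rng.integers(3, 9)
        x = rng.integers(0, 5, size=n).astype(float)  # ties likely
        y = rng.integers(0, 5, size=n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        tau, _ = kendall_correlation(x, y)
        assert tau == pytest.approx(kendall_tau_b_oracle(x, y), abs=1e-12)


def test_kendall_exact_p_matches_enumeration(rng):
    for n in (4, 5, 6, 8, 10):
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        _, p = kendall_correlation(x, y)
        assert p == pytest.approx(kendall_exact_p_oracle(x, y), abs=1e-12)


def test_fasting_delta_examples():
    before = pd.DataFrame({"fish_id": ["a", "b"], "noa_total": [4, 7],
                           "dir_total_s": [2.0, 3.0]})
    after = pd.DataFrame({"fish_id": ["b", "a"], "noa_total": [7, 10],
                          "dir_total_s": [3.0, 2.0]})
    d = fasting_delta(before, after)
    assert d.loc[d.fish_id == "a", "delta_noa_total"].item() == 6
    assert d.loc[d.fish_id == "b", "delta_noa_total"].item() == 0
    assert (d.delta_dir_total_s == 0).all()


def test_fasting_delta_rejects_unmatched_ids():
    before = pd.DataFrame({"fish_id": ["a", "b"], "noa_total": [1, 2]})
    after = pd.DataFrame({"fish_id": ["a", "c"], "noa_total": [1, 2]})
    with pytest.raises(ValueError, match="c"):
        fasting_delta(before, after, measures=("noa_total",))


def test_fasting_delta_correlation_recovery(rng):
    # cohort built so that the fasting change in approach count decreases in
    # rank with the left-side neuromast count: tau must come back negative
    n = 40
    sn_left = rng.integers(5, 60, size=n)
    delta = -sn_left + rng.normal(0, 5, size=n)
    before = pd.DataFrame({"fish_id": range(n), "noa_total": 20})
    after = pd.DataFrame({"fish_id": range(n), "noa_total": 20 + delta})
    d = fasting_delta(before, after, measures=("noa_total",))
    tau, p = kendall_correlation(sn_left, d["delta_noa_total"])
    assert tau < -0.5
    assert p < 1e-6


def test_holm_step_down_hand_computation():
    # step-down by hand for a family of two: p_(1) doubles, p_(2) is then
    # max(2 * 0.01, 1 * 0.04) = 0.04
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.04], method="holm")[1]
    assert adj == pytest.approx([0.02, 0.04])


def test_paired_wilcoxon_holm_table():
    before = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    shifted = before + 1.0
    table = paired_wilcoxon_holm({
        "shifted": (before, shifted),
        "identical": (before, before),
        "noisy": (before, before + np.array([1, -1, 1, -1, 1, -1.0])),
    })
    shifted_row = table.set_index("test").loc["shifted"]
    assert shifted_row.p_raw == pytest.approx(0.03125)  # extreme one-sided x2
    ident = table.set_index("test").loc["identical"]
    assert math.isnan(ident.p_raw) and "undefined" in ident.note
    # Holm over the two defined tests only
    defined = table.dropna(subset=["p_raw"]).sort_values("p_raw")
    assert defined.iloc[0].p_holm == pytest.approx(
        min(1.0, 2 * defined.iloc[0].p_raw))


def test_single_test_family_holm_is_identity():
    before = np.arange(1.0, 9.0)
    table = paired_wilcoxon_holm({"only": (before, before + 1)})
    assert table.p_holm[0] == pytest.approx(table.p_raw[0])
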