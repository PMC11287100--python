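"""Association statistics: oracles, split balance, gating, adjustment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stepfit import (
    compare_groups,
    describe_distribution,
    holm_adjust,
    median_split,
    partial_spearman,
    rin_transform,
    shapiro_wilk,
    spearman,
    tertile_split,
)
from stepfit.stats import CollinearityError


def test_spearman_monotone_extremes():
    x = [1.0, 2.0, 5.0, 9.0, 12.0]
    assert spearman(x, [v**3 for v in x]).rho == pytest.approx(1.0)
    assert spearman(x, x[::-1]).rho == pytest.approx(-1.0)


def test_spearman_matches_scipy_on_fuzzed_pairs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(5, 60))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        if rng.random() < 0.5:  # inject ties
            x = np.round(x, 1)
            y = np.round(y, 1)
        got = spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert got.rho == pytest.approx(rho, abs=1e-12)
        assert got.p == pytest.approx(p, abs=1e-12)


def test_spearman_invariant_to_monotone_transform_and_symmetric():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=40), rng.normal(size=40)
    base = spearman(x, y).rho
    assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
    assert spearman(y, x).rho == pytest.approx(base, abs=1e-12)


def test_spearman_missing_and_degenerate():
    assert math.isnan(spearman([1, 2], [3, 4]).rho)
    got = spearman([1, 2, 3, np.nan], [2, 4, 6, 8])
    assert got.n == 3 and got.rho == pytest.approx(1.0)
    assert math.isnan(spearman([5, 5, 5, 5], [1, 2, 3, 4]).rho)


def test_partial_spearman_reduces_and_matches_pingouin():
    rng = np.random.default_rng(2)
    n = 60
    z = rng.normal(size=n)
    x = 0.5 * z + rng.normal(size=n)
    y = -0.3 * z + rng.normal(size=n)
    cov = pd.DataFrame({"z": z, "w": rng.normal(size=n)})

    assert partial_spearman(x, y, None).rho == pytest.approx(
        spearman(x, y).rho, abs=1e-12
    )

    got = partial_spearman(x, y, cov)
    pingouin = pytest.importorskip("pingouin")
    df = pd.DataFrame({"x": x, "y": y, "z": z, "w": cov["w"]})
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"],
                                method="spearman")
    p_col = "p_val" if "p_val" in ref.columns else "p-val"
    assert got.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
    assert got.p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-9)


def test_partial_spearman_construction_cases():
    rng = np.random.default_rng(3)
    n = 500
    cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    x, y = rng.normal(size=n), rng.normal(size=n)
    # independent covariates barely move the estimate
    assert partial_spearman(x, y, cov).rho == pytest.approx(
        spearman(x, y).rho, abs=0.05
    )
    # x fully determined by a covariate -> partial association vanishes
    x2 = 2.0 * cov["a"].to_numpy()
    y2 = 0.8 * cov["a"].to_numpy() + 0.1 * rng.normal(size=n)
    assert abs(partial_spearman(x2, y2, cov[["a"]]).rho) < 0.05


def test_partial_spearman_collinearity_names_column():
    rng = np.random.default_rng(4)
    n = 30
    a = rng.normal(size=n)
    cov = pd.DataFrame({"a": a, "dup": 2 * a + 1})
    with pytest.raises(CollinearityError, match="dup|a"):
        partial_spearman(rng.normal(size=n), rng.normal(size=n), cov)


def test_tertile_split_sizes_and_ties():
    s = tertile_split(list(range(9)))
    counts = {lab: s.labels.count(lab) for lab in ("low", "medium", "high")}
    assert counts == {"low": 3, "medium": 3, "high": 3}

    s10 = tertile_split(list(range(10)))
    sizes = sorted(
        (s10.labels.count(lab) for lab in ("low", "medium", "high")), reverse=True
    )
    assert sizes == [4, 3, 3]

    tied = tertile_split([7.0] * 9)
    counts = {lab: tied.labels.count(lab) for lab in ("low", "medium", "high")}
    assert counts == {"low": 3, "medium": 3, "high": 3}
    # stable order: the first three inputs land in "low"
    assert tied.labels[:3] == ["low"] * 3

    with pytest.raises(ValueError):
        tertile_split([1.0, 2.0])


def test_tertile_labels_follow_value_order():
    s = tertile_split([30, 10, 20, 60, 40, 50])
    assert s.labels[1] == "low" and s.labels[3] == "high"


def test_median_split_balance():
    s = median_split([1.0, 2.0, 3.0, 4.0])
    assert s.labels == ["low", "low", "high", "high"]
    tied = median_split([1.0, 2.0, 2.0, 3.0])
    assert tied.labels.count("low") == 2 and tied.labels.count("high") == 2
    rng = np.random.default_rng(5)
    for _ in range(50):
        vals = rng.integers(0, 4, size=int(rng.integers(2, 30))).astype(float)
        s = median_split(vals)
        assert abs(s.labels.count("low") - s.labels.count("high")) <= 1
        t = tertile_split(vals) if len(vals) >= 3 else None
        if t:
            sizes = [t.labels.count(lab) for lab in ("low", "medium", "high")]
            assert max(sizes) - min(sizes) <= 1


def test_shapiro_wilk_calibration():
    rng = np.random.default_rng(6)
    normal_ok = sum(
        shapiro_wilk(rng.normal(size=500))[1] > 0.05 for _ in range(100)
    )
    assert normal_ok >= 95
    expo_caught = sum(
        shapiro_wilk(rng.exponential(size=100))[1] < 0.05 for _ in range(100)
    )
    assert expo_caught >= 99
    with pytest.raises(ValueError):
        shapiro_wilk([3.0] * 10)
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])


def test_compare_groups_gate_and_power():
    rng = np.random.default_rng(7)
    a = rng.normal(size=30)
    same = compare_groups(a, a)
    assert same.p_raw == pytest.approx(1.0, abs=1e-9)

    shifted = compare_groups(rng.normal(size=30), rng.normal(2.0, 1.0, size=30))
    assert shifted.test == "welch_t" and shifted.p_raw < 0.001
    assert math.isfinite(shifted.df)

    skewed = compare_groups(rng.lognormal(size=40), rng.lognormal(size=40))
    assert skewed.test == "mann_whitney"
    assert min(skewed.normality_gate) < 0.05


def test_holm_ladder_and_properties():
    got = holm_adjust([0.01, 0.04, 0.03])
    assert got == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    for _ in range(50):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 8)))
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # independent reference implementation
        assert adj == pytest.approx(multipletests(p, method="holm")[1], abs=1e-12)
    with pytest.raises(ValueError):
        holm_adjust([0.0, 0.5])


def test_holm_controls_familywise_error_under_three_nulls():
    rng = np.random.default_rng(9)
    reps = 5000
    rejections = 0
    for _ in range(reps):
        p = rng.uniform(size=3)  # three true nulls
        if np.any(holm_adjust(p) <= 0.05):
            rejections += 1
    assert rejections / reps <= 0.06


def test_describe_distribution_shapes():
    rng = np.random.default_rng(10)
    d = describe_distribution(rng.normal(size=1000))
    assert abs(d.skewness) < 0.2 and abs(d.kurtosis) < 0.5

    piled = np.concatenate([np.full(20, 20.0), rng.uniform(9, 19, size=80)])
    piled = np.concatenate([piled, np.full(10, 20.0)])  # >20% at ceiling
    dd = describe_distribution(piled, max_possible=20.0)
    assert dd.ceiling_percent == pytest.approx(100 * 30 / 110, abs=0.1)

    skew_left = np.concatenate([np.full(30, 20.0), rng.uniform(0, 19, 15)])
    assert describe_distribution(skew_left, 20.0).skewness < -0.5

    dc = describe_distribution([5.0, 5.0, 5.0])
    assert dc.sd == 0 and math.isnan(dc.skewness)


def test_rin_transform_properties():
    rng = np.random.default_rng(11)
    x = rng.normal(size=200)
    z = rin_transform(x)
    assert np.corrcoef(x, z)[0, 1] > 0.99
    assert abs(z.mean()) < 0.05 and abs(z.std(ddof=1) - 1) < 0.05
    tied = rin_transform([1.0, 3.0, 3.0, 9.0])
    assert tied[1] == pytest.approx(tied[2])
    with_nan = rin_transform([1.0, np.nan, 2.0])
    assert math.isnan(with_nan[1]) and math.isfinite(with_nan[0])


def test_spearman_type1_error_calibrated_at_cohort_size():
    rng = np.random.default_rng(12)
    n, reps = 86, 2000
    hits = 0
    for _ in range(reps):
        if spearman(rng.normal(size=n), rng.normal(size=n)).p < 0.05:
            hits += 1
    assert 0.035 <= hits / reps <= 0.065


# --- hypothesis property: Holm dominates raw p and keeps order ----------

from hypothesis import given, settings, strategies as st


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                max_size=12))
def test_holm_adjustment_properties(pvals):
    p = np.asarray(pvals)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
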