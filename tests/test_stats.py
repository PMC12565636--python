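"""Paired t-tests, Cohen's d, Bonferroni, and comparison tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazeseq import (
    ComparisonSpec,
    bonferroni_alpha,
    cohens_d_from_t,
    format_report,
    paired_t,
    run_comparisons,
)


def test_identical_vectors_null_result():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = paired_t(x, x)
    assert res.t == 0.0 and res.p == 1.0 and res.d == 0.0
    assert res.df == 3


def test_textbook_formula_oracle():
    # independent hand evaluation of t = mean_diff / (sd_diff / sqrt(5))
    x = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
    y = np.array([8.0, 11.0, 10.0, 10.0, 9.0])
    diff = x - y
    mean_d = diff.mean()
    sd_d = diff.std(ddof=1)
    expected_t = mean_d / (sd_d / math.sqrt(5))
    res = paired_t(x, y)
    assert res.t == pytest.approx(expected_t, rel=1e-12)
    assert res.d == pytest.approx(mean_d / sd_d, rel=1e-12)
    assert res.df == 4
    assert res.mean_diff == pytest.approx(mean_d)
    assert res.sd_diff == pytest.approx(sd_d)


def test_matches_scipy_ttest_rel():
    rng = np.random.default_rng(21)
    for _ in range(20):
        x = rng.normal(size=15)
        y = rng.normal(0.3, 1.0, size=15)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)


def test_sign_symmetry():
    rng = np.random.default_rng(22)
    x = rng.normal(size=12)
    y = rng.normal(0.5, 1.0, size=12)
    ab = paired_t(x, y)
    ba = paired_t(y, x)
    assert ab.t == pytest.approx(-ba.t)
    assert ab.d == pytest.approx(-ba.d)
    assert ab.p == pytest.approx(ba.p)
    # t and d flip sign together, and d = t / sqrt(n) exactly
    assert ab.d == pytest.approx(ab.t / math.sqrt(ab.n_pairs), abs=1e-12)


def test_pairwise_deletion():
    x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
    y = np.array([0.5, 2.0, np.nan, 3.0, 4.5])
    res = paired_t(x, y)
    assert res.n_pairs == 3
    assert res.df == 2


def test_degenerate_inputs():
    with pytest.raises(ValueError, match="2 complete pairs"):
        paired_t([1.0], [2.0])
    with pytest.raises(ValueError, match="zero variance"):
        paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])  # constant non-zero diff


@pytest.mark.parametrize(
    "t, n, expected",
    [
        (-2.71, 34, -0.46),
        (-2.16, 34, -0.37),
        (-1.61, 34, -0.28),
        (1.98, 34, 0.34),
        (0.0, 10, 0.0),
    ],
)
def test_cohens_d_from_t(t, n, expected):
    assert round(cohens_d_from_t(t, n), 2) == expected


def test_cohens_d_needs_two(n=1):
    with pytest.raises(ValueError, match="n"):
        cohens_d_from_t(1.0, n)


@pytest.mark.parametrize("alpha, m, expected", [(0.05, 2, 0.025), (0.05, 1, 0.05), (0.05, 5, 0.01)])
def test_bonferroni(alpha, m, expected):
    assert bonferroni_alpha(alpha, m) == pytest.approx(expected)


def _toy_table():
    rows = []
    vals = {
        ("p1", "a"): 1.0, ("p1", "b"): 0.5,
        ("p2", "a"): 0.8, ("p2", "b"): 0.6,
    }
    for (p, c), v in vals.items():
        rows.append(
            {"participant": p, "trial": 0, "condition": c, "excluded": False,
             "metric": "similarity", "aoi": "", "value": v}
        )
    return pd.DataFrame(rows)


def test_run_comparisons_composes_paired_t():
    table = _toy_table()
    spec = ComparisonSpec(metric="similarity", condition_a="a", condition_b="b")
    out = run_comparisons(table, [spec])
    assert len(out) == 1
    row = out.iloc[0]
    ref = paired_t([1.0, 0.8], [0.5, 0.6])
    assert row["t"] == pytest.approx(ref.t)
    assert row["p"] == pytest.approx(ref.p)
    assert row["d"] == pytest.approx(row["t"] / math.sqrt(row["n_pairs"]), abs=1e-9)


def test_run_comparisons_aggregates_trials_per_participant():
    rows = []
    for trial, v in enumerate([0.2, 0.4]):  # participant p1, condition a: mean 0.3
        rows.append({"participant": "p1", "trial": trial, "condition": "a",
                     "excluded": False, "metric": "similarity", "aoi": "", "value": v})
    rows.append({"participant": "p1", "trial": 0, "condition": "b", "excluded": False,
                 "metric": "similarity", "aoi": "", "value": 0.1})
    rows.append({"participant": "p2", "trial": 0, "condition": "a", "excluded": False,
                 "metric": "similarity", "aoi": "", "value": 0.5})
    rows.append({"participant": "p2", "trial": 0, "condition": "b", "excluded": False,
                 "metric": "similarity", "aoi": "", "value": 0.2})
    out = run_comparisons(pd.DataFrame(rows), [
        ComparisonSpec(metric="similarity", condition_a="a", condition_b="b")
    ])
    ref = paired_t([0.3, 0.5], [0.1, 0.2])
    assert out.iloc[0]["t"] == pytest.approx(ref.t)


def test_run_comparisons_missing_condition_raises():
    table = _toy_table()
    spec = ComparisonSpec(metric="similarity", condition_a="a", condition_b="zzz")
    with pytest.raises(ValueError, match="'zzz'"):
        run_comparisons(table, [spec])


def test_run_comparisons_excluded_rows_dropped():
    table = _toy_table()
    extra = table.iloc[[0]].assign(value=1000.0, excluded=True)
    out_with = run_comparisons(pd.concat([table, extra]), [
        ComparisonSpec(metric="similarity", condition_a="a", condition_b="b")
    ])
    out_without = run_comparisons(table, [
        ComparisonSpec(metric="similarity", condition_a="a", condition_b="b")
    ])
    assert out_with.iloc[0]["t"] == pytest.approx(out_without.iloc[0]["t"])


def test_bonferroni_flag_in_table():
    table = _toy_table()
    spec = ComparisonSpec(
        metric="similarity", condition_a="a", condition_b="b",
        correction="bonferroni", m=2,
    )
    out = run_comparisons(table, [spec])
    assert out.iloc[0]["alpha_adjusted"] == pytest.approx(0.025)


def test_format_report_rounding():
    table = _toy_table()
    out = run_comparisons(table, [
        ComparisonSpec(metric="similarity", condition_a="a", condition_b="b", name="toy")
    ])
    text = format_report(out)
    assert "toy" in text
    assert f"t({int(out.iloc[0]['df'])})=" in text
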