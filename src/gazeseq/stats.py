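"""Paired condition comparisons: two-tailed t-tests, Cohen's d, Bonferroni.

Comparisons pair at participant level: each participant's qualifying trials
of a condition are aggregated (mean by default) to one value, pairs with a
missing member are deleted, and the paired t statistic is

    t = mean_diff / (sd_diff / sqrt(n)),   df = n - 1,

with the two-tailed p from the t distribution. The paired effect size is
Cohen's d = mean_diff / sd_diff, which satisfies d = t / sqrt(n) exactly —
the identity used to recover printed effect sizes from printed t values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonSpec",
    "PairedTestResult",
    "paired_t",
    "cohens_d_from_t",
    "bonferroni_alpha",
    "run_comparisons",
    "format_report",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One paired comparison: a metric, two conditions, optional AOI and family."""

    metric: str  # distance | similarity | similarity_pct | ttff | dwell | n_fix
    condition_a: str
    condition_b: str
    aoi: str | None = None
    alpha: float = 0.05
    correction: str = "none"  # none | bonferroni
    m: int = 1  # comparisons in the family (for bonferroni)
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class PairedTestResult:
    n_pairs: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    d: float
    alpha_adjusted: float = 0.05


def paired_t(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> PairedTestResult:
    """Two-tailed paired t-test with pairwise deletion of missing values.

    Degenerate case: sd_diff = 0 with mean_diff = 0 gives t = 0, p = 1, d = 0
    (identical paired values carry no evidence); sd_diff = 0 with a non-zero
    mean difference is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    diff = x - y
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0.0:
        if mean_diff != 0.0:
            raise ValueError("degenerate data: zero variance of differences with non-zero mean")
        t_stat, p, d = 0.0, 1.0, 0.0
    else:
        t_stat = mean_diff / (sd_diff / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
        d = mean_diff / sd_diff
    return PairedTestResult(
        n_pairs=n,
        mean_a=float(x.mean()),
        sd_a=float(x.std(ddof=1)),
        mean_b=float(y.mean()),
        sd_b=float(y.std(ddof=1)),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        t=float(t_stat),
        df=n - 1,
        p=p,
        d=float(d),
        alpha_adjusted=alpha,
    )


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired Cohen's d recovered from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return t / math.sqrt(n)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance level for a family of m comparisons."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def run_comparisons(
    table: pd.DataFrame,
    specs: Sequence[ComparisonSpec],
    agg: str = "mean",
) -> pd.DataFrame:
    """Run each paired comparison on a tidy metrics table.

    ``table`` is the long format of :func:`gazeseq.metrics.metrics_table`.
    Excluded trials are dropped; values are aggregated to one per participant
    per condition (``agg``: mean default, median supported) before pairing.
    Missing values (e.g. TTFF with no fixation in the AOI) are skipped in the
    aggregation and deleted pairwise in the test.
    """
    if agg not in ("mean", "median"):
        raise ValueError(f"agg must be 'mean' or 'median', got {agg!r}")
    rows = []
    for spec in specs:
        sub = table[~table["excluded"].astype(bool)]
        sub = sub[sub["metric"] == spec.metric]
        if spec.aoi is not None:
            sub = sub[sub["aoi"] == spec.aoi]
        present = set(sub["condition"].unique())
        for cond in (spec.condition_a, spec.condition_b):
            if cond not in present:
                raise ValueError(
                    f"condition {cond!r} not present in metrics table for "
                    f"metric {spec.metric!r}"
                    + (f", AOI {spec.aoi!r}" if spec.aoi is not None else "")
                )
        piv = sub.pivot_table(
            index="participant", columns="condition", values="value", aggfunc=agg
        )
        res = paired_t(
            piv[spec.condition_a].to_numpy(),
            piv[spec.condition_b].to_numpy(),
            alpha=spec.alpha,
        )
        alpha_adj = (
            bonferroni_alpha(spec.alpha, spec.m)
            if spec.correction == "bonferroni"
            else spec.alpha
        )
        rows.append(
            {
                "comparison": spec.name
                or f"{spec.metric}:{spec.condition_a}-vs-{spec.condition_b}",
                "metric": spec.metric,
                "aoi": "" if spec.aoi is None else spec.aoi,
                "condition_a": spec.condition_a,
                "condition_b": spec.condition_b,
                "n_pairs": res.n_pairs,
                "mean_a": res.mean_a,
                "sd_a": res.sd_a,
                "mean_b": res.mean_b,
                "sd_b": res.sd_b,
                "mean_diff": res.mean_diff,
                "sd_diff": res.sd_diff,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "d": res.d,
                "alpha": spec.alpha,
                "alpha_adjusted": alpha_adj,
                "significant": res.p < spec.alpha,
                "significant_adjusted": res.p < alpha_adj,
            }
        )
    return pd.DataFrame(rows)


def format_report(results: pd.DataFrame) -> str:
    """Plain-text report: M (SD) per condition, t, df, p, d (t and d to 2 dp, p to 3 dp)."""
    lines = [
        f"{'Comparison':<42} {'AOI':<4} {'Condition':<16} {'M (SD)':>20} "
        f"{'t(df)':>12} {'p':>7} {'d':>7}"
    ]
    for _, r in results.iterrows():
        star = " *" if r["significant_adjusted"] else ""
        lines.append(
            f"{r['comparison']:<42} {r['aoi'] or '-':<4} {r['condition_a']:<16} "
            f"{r['mean_a']:>11.2f} ({r['sd_a']:.2f})"
            f" {'t(' + str(r['df']) + ')=' + format(r['t'], '.2f'):>12}"
            f" {r['p']:>7.3f} {r['d']:>7.2f}{star}"
        )
        lines.append(
            f"{'':<42} {'':<4} {r['condition_b']:<16} "
            f"{r['mean_b']:>11.2f} ({r['sd_b']:.2f})"
        )
    return "\n".join(lines) + "\n"
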