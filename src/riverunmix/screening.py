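"""Tracer screening: range test, one-way ANOVA with Tukey HSD, normality EDA.

The screening philosophy is deliberately light-touch: a tracer is kept when
the mixture values plausibly lie inside the span of the candidate sources
(range test), discrimination between source groups is described by ANOVA and
Tukey's honestly-significant-difference comparisons, and normality is only
summarised (Shapiro-Wilk p plus histogram counts), never used as a hard
filter. Expert include/exclude overrides are applied after the automatic step
and flagged as manual decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_report import SourceSet, TracerTable

__all__ = [
    "RangeTestResult",
    "AnovaResult",
    "TukeyResult",
    "ScreeningPolicy",
    "ScreeningReport",
    "range_test",
    "one_way_anova",
    "tukey_hsd",
    "normality_summary",
    "screen_panel",
]


@dataclass
class RangeTestResult:
    tracer: str
    source_min: float
    source_max: float
    in_range_fraction: float
    passed: bool
    inside: np.ndarray  # per-mixture-sample containment flags

    def __post_init__(self) -> None:
        assert 0.0 <= self.in_range_fraction <= 1.0


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyResult:
    """All pairwise source-group comparisons via the studentized range."""

    pairs: pd.DataFrame  # columns: group_a, group_b, diff, q, p_adj, significant
    alpha: float

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairs[self.pairs["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


@dataclass
class ScreeningPolicy:
    """Range-test threshold, bound convention and manual overrides."""

    threshold: float = 0.5
    bounds: str = "minmax"  # minmax | whisker (1.5 x IQR)
    summary_bounds: bool = False  # opt-in mean +/- 2 SD bounds for summary-mode sources
    manual_exclude: Sequence[str] = field(default_factory=list)
    manual_include: Sequence[str] = field(default_factory=list)


@dataclass
class ScreeningReport:
    retained: list[str]
    table: pd.DataFrame  # tracer, source_min, source_max, fraction, passed, decision, reason


def _pooled_source_values(source_set: SourceSet, tracer: str) -> np.ndarray:
    vals = [g.raw[tracer].to_numpy(float) for g in source_set.groups.values()]
    return np.concatenate(vals)


def _bounds(source_set: SourceSet, tracer: str, policy: ScreeningPolicy) -> tuple[float, float]:
    if source_set.has_raw():
        pooled = _pooled_source_values(source_set, tracer)
        if policy.bounds == "minmax":
            return float(pooled.min()), float(pooled.max())
        if policy.bounds == "whisker":
            q1, q3 = np.percentile(pooled, [25, 75])
            iqr = q3 - q1
            return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)
        raise ValueError(f"unknown bounds convention {policy.bounds!r}")
    if not policy.summary_bounds:
        raise ValueError(
            "summary-mode sources have no raw samples for min/max bounds; "
            "opt in to the mean ± 2·SD fallback with ScreeningPolicy(summary_bounds=True)"
        )
    lo, hi = np.inf, -np.inf
    for g in source_set.groups.values():
        m = g.moments().loc[tracer]
        lo = min(lo, m["mean"] - 2.0 * m["sd"])
        hi = max(hi, m["mean"] + 2.0 * m["sd"])
    return float(lo), float(hi)


def range_test(
    source_set: SourceSet,
    tracer_table: TracerTable,
    threshold: float = 0.5,
    policy: ScreeningPolicy | None = None,
) -> dict[str, RangeTestResult]:
    """Containment test of mixture values within the pooled source span.

    For each tracer the bounds are the min/max over all source samples pooled
    across groups at the node (whisker bounds optional); a mixture sample is
    inside iff ``source_min <= y <= source_max``. A tracer passes when the
    inside fraction reaches ``threshold``.
    """
    policy = policy or ScreeningPolicy(threshold=threshold)
    out: dict[str, RangeTestResult] = {}
    for tracer in tracer_table.panel:
        if tracer not in source_set.panel:
            raise ValueError(f"tracer {tracer!r} absent from source panel")
        lo, hi = _bounds(source_set, tracer, policy)
        y = tracer_table.values_for(tracer)
        inside = (y >= lo) & (y <= hi)
        frac = float(inside.mean())
        out[tracer] = RangeTestResult(
            tracer=tracer,
            source_min=lo,
            source_max=hi,
            in_range_fraction=frac,
            passed=frac >= policy.threshold,
            inside=inside,
        )
    return out


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs >= 2 values")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: zero within-group variance")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ssw == 0:
        raise ValueError("zero within-group variance")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA across source groups."""
    arrs = _as_groups(groups)
    F, p = stats.f_oneway(*arrs)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n - k, p=float(p))


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    names: Sequence[str] | None = None,
) -> TukeyResult:
    """Tukey(-Kramer) HSD pairwise comparisons after a one-way ANOVA.

    Adjusted p-values come from the studentized-range distribution with the
    ANOVA within-group degrees of freedom; unbalanced designs use the
    Tukey-Kramer standard error.
    """
    arrs = _as_groups(groups)
    names = list(names) if names is not None else [f"g{i}" for i in range(len(arrs))]
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    df_w = n - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    res = stats.tukey_hsd(*arrs)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = arrs[i].mean() - arrs[j].mean()
        se = np.sqrt(msw * 0.5 * (1.0 / len(arrs[i]) + 1.0 / len(arrs[j])))
        q = abs(diff) / se
        p_adj = float(res.pvalue[i, j])
        rows.append(
            dict(
                group_a=names[i],
                group_b=names[j],
                diff=float(diff),
                q=float(q),
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    return TukeyResult(pairs=pd.DataFrame(rows), alpha=alpha)


def normality_summary(values: Sequence[float], bins: int = 10) -> dict:
    """Shapiro-Wilk p and histogram counts; descriptive only, never a filter."""
    x = np.asarray(values, float)
    counts, edges = np.histogram(x, bins=bins)
    if len(x) >= 3 and np.ptp(x) > 0:
        shapiro_p = float(stats.shapiro(x).pvalue)
    else:
        shapiro_p = float("nan")
    return {
        "n": int(len(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else float("nan"),
        "shapiro_p": shapiro_p,
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }


def screen_panel(
    source_set: SourceSet,
    tracer_table: TracerTable,
    policy: ScreeningPolicy | None = None,
) -> ScreeningReport:
    """Apply the range test to the full panel, then manual overrides.

    Overrides mirror expert-judgement removals (e.g. withdrawing tracers on
    fluvial-sorting grounds even when they pass the range test); they are
    applied after the automatic step and labelled ``manual`` in the report.
    """
    policy = policy or ScreeningPolicy()
    results = range_test(source_set, tracer_table, policy=policy)
    rows = []
    retained: list[str] = []
    for tracer in tracer_table.panel:
        r = results[tracer]
        decision, reason = ("retain", "range test") if r.passed else ("drop", "range test")
        if tracer in policy.manual_exclude:
            decision, reason = "drop", "manual"
        elif tracer in policy.manual_include:
            decision, reason = "retain", "manual"
        if decision == "retain":
            retained.append(tracer)
        rows.append(
            dict(
                tracer=tracer,
                source_min=r.source_min,
                source_max=r.source_max,
                fraction=r.in_range_fraction,
                passed=r.passed,
                decision=decision,
                reason=reason,
            )
        )
    if not retained:
        raise ValueError(
            "screening eliminated every tracer; review the range-test threshold"
        )
    return ScreeningReport(retained=retained, table=pd.DataFrame(rows))
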