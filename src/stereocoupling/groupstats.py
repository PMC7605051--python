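"""Frequentist group-level analyses of the simulated experiments.

Per subject: percent "convex" per signed disparity level (the two 0-arcmin
conditions are pooled), percent correct coupling per inducer condition, and a
depth-perception score (% convex at +4.6 minus % convex at -4.6 arcmin, so
disparity-sensitive subjects score high).  Group level: one-way ANOVA of the
per-subject percentages over the five levels, one-sample t tests against
chance (50%), a paired near-vs-far t test, and an ordinary least-squares fit
of coupling (0-1 fraction scale) on depth perception.

The ANOVA deliberately treats per-subject percentages at each level as
independent observations — giving df (levels-1, N*levels - levels) — because
that is the design the analysis reproduces, not a repeated-measures model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectSummary",
    "TestResult",
    "summarize_subject",
    "summarize_cohort",
    "one_way_anova",
    "one_sample_t",
    "paired_t",
    "depth_perception_score",
    "linear_fit",
    "group_analysis",
]

BASELINE_LEVELS = (-4.6, -2.3, 0.0, 2.3, 4.6)


@dataclass
class SubjectSummary:
    subject_id: str
    pct_convex_by_level: dict[float, float]
    pct_coupling_near: float | None
    pct_coupling_far: float | None
    n_by_level: dict[float, int]
    incomplete: bool
    group: str | None = None

    @property
    def depth_perception(self) -> float:
        return depth_perception_score(self)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: int | tuple[int, int]
    p_value: float


def summarize_subject(responses: pd.DataFrame) -> SubjectSummary:
    """Per-level and per-condition percentages for a single subject."""
    sids = responses["subject_id"].unique()
    if len(sids) != 1:
        raise ValueError("summarize_subject expects exactly one subject")
    base = responses[responses["experiment"] == "baseline"]
    pct, n_by = {}, {}
    for level in sorted(base["disparity_arcmin"].unique()):
        sel = base[base["disparity_arcmin"] == level]
        pct[float(level)] = 100.0 * (sel["response"] == "convex").mean()
        n_by[float(level)] = int(len(sel))
    coup = responses[responses["experiment"] == "coupling"]

    def coupling_pct(cond: str) -> float | None:
        sel = coup[coup["condition"] == cond]
        if len(sel) == 0:
            return None
        return 100.0 * sel["coupled_correct"].astype(bool).mean()

    incomplete = any(lv not in pct for lv in BASELINE_LEVELS)
    return SubjectSummary(
        subject_id=str(sids[0]),
        pct_convex_by_level=pct,
        pct_coupling_near=coupling_pct("near"),
        pct_coupling_far=coupling_pct("far"),
        n_by_level=n_by,
        incomplete=incomplete,
    )


def summarize_cohort(responses: pd.DataFrame) -> dict[str, SubjectSummary]:
    return {
        str(sid): summarize_subject(responses[responses["subject_id"] == sid])
        for sid in dict.fromkeys(responses["subject_id"])
    }


def depth_perception_score(summary: SubjectSummary) -> float:
    """% convex at +4.6 minus % convex at -4.6 arcmin (percentage points)."""
    pct = summary.pct_convex_by_level
    if 4.6 not in pct or -4.6 not in pct:
        raise ValueError(f"subject {summary.subject_id} lacks the extreme disparity levels")
    return pct[4.6] - pct[-4.6]


def one_way_anova(values_by_level: dict[float, np.ndarray]) -> TestResult:
    """One-way ANOVA of per-subject percentages across disparity levels."""
    groups = [np.asarray(v, dtype=float) for v in values_by_level.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 levels with >= 2 subjects each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = all_vals.size - len(groups)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("F statistic undefined: no variance between or within levels")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult("one-way ANOVA", float(f), (df1, df2), p)


def one_sample_t(values: np.ndarray, mu: float = 50.0) -> TestResult:
    """Two-sided one-sample t test (default: against the 50% chance level)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or values.std(ddof=1) == 0:
        raise ValueError("t statistic undefined: need >= 2 values with nonzero variance")
    res = stats.ttest_1samp(values, mu)
    return TestResult("one-sample t", float(res.statistic), values.size - 1, float(res.pvalue))


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Paired t test: one-sample t on the differences against 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if diff.size < 2 or diff.std(ddof=1) == 0:
        raise ValueError("t statistic undefined: differences have zero variance")
    res = stats.ttest_rel(a, b)
    return TestResult("paired t", float(res.statistic), diff.size - 1, float(res.pvalue))


def linear_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS fit of y on x with Pearson r, residual SSE and df = n - 2.

    For the coupling-vs-depth analysis, x is the depth-perception score in
    percentage points and y the coupling fraction on the 0-1 scale (the SSE is
    only meaningful on that scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: x is constant")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "sse": float((resid**2).sum()),
        "df": int(x.size - 2),
    }


def _safe(test, *args, **kwargs):
    try:
        r = test(*args, **kwargs)
        return {"test_name": r.test_name, "statistic": r.statistic,
                "df": list(r.df) if isinstance(r.df, tuple) else r.df,
                "p_value": r.p_value}
    except ValueError as err:
        return {"error": str(err)}


def group_analysis(
    summaries: dict[str, SubjectSummary],
    groups: dict[str, str],
) -> dict:
    """The full battery of group statistics, per classified group.

    ``groups`` maps subject_id -> group label.  For each group: ANOVA over the
    five baseline levels, per-level t tests against 50%, near/far coupling t
    tests against 50%, paired near-vs-far; plus the far-coupling-vs-depth OLS
    fit within the stereoscopic group.
    """
    out: dict = {"groups": {}}
    for label in sorted(set(groups.values())):
        members = [s for s in summaries.values()
                   if groups.get(s.subject_id) == label and not s.incomplete]
        if len(members) < 2:
            out["groups"][label] = {"n": len(members), "note": "too few subjects"}
            continue
        by_level = {
            lv: np.array([m.pct_convex_by_level[lv] for m in members])
            for lv in BASELINE_LEVELS
        }
        near = np.array([m.pct_coupling_near for m in members], dtype=float)
        far = np.array([m.pct_coupling_far for m in members], dtype=float)
        entry = {
            "n": len(members),
            "members": [m.subject_id for m in members],
            "anova_disparity": _safe(one_way_anova, by_level),
            "t_vs_chance_by_level": {
                str(lv): _safe(one_sample_t, v) for lv, v in by_level.items()
            },
            "mean_pct_by_level": {str(lv): float(v.mean()) for lv, v in by_level.items()},
            "sem_pct_by_level": {
                str(lv): float(v.std(ddof=1) / np.sqrt(len(v))) for lv, v in by_level.items()
            },
            "coupling_near_vs_chance": _safe(one_sample_t, near),
            "coupling_far_vs_chance": _safe(one_sample_t, far),
            "coupling_near_vs_far": _safe(paired_t, near, far),
            "mean_coupling": {"near": float(near.mean()), "far": float(far.mean())},
        }
        if label == "stereoscopic":
            try:
                depth = np.array([m.depth_perception for m in members])
                entry["far_coupling_vs_depth_fit"] = linear_fit(depth, far / 100.0)
                entry["near_coupling_vs_depth_fit"] = linear_fit(depth, near / 100.0)
            except ValueError as err:
                entry["far_coupling_vs_depth_fit"] = {"error": str(err)}
        out["groups"][label] = entry
    return out
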