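import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stereocoupling.groupstats import (
    depth_perception_score,
    group_analysis,
    linear_fit,
    one_sample_t,
    one_way_anova,
    paired_t,
    summarize_cohort,
    summarize_subject,
)
from stereocoupling.observers import RESPONSE_COLUMNS


def _baseline_df(counts_by_level, sid="s1"):
    """counts_by_level: {signed level: (n_convex, n_total)}"""
    rows = []
    i = 0
    for level, (k, n) in counts_by_level.items():
        for j in range(n):
            shape = "convex" if level > 0 or (level == 0 and j % 2 == 0) else "concave"
            rows.append((sid, "baseline", i, level, shape,
                         "convex" if j < k else "concave", None))
            i += 1
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


FULL = {-4.6: (0, 20), -2.3: (5, 20), 0.0: (20, 40), 2.3: (15, 20), 4.6: (20, 20)}


class TestSummaries:
    def test_percentages_and_pooled_zero(self):
        s = summarize_subject(_baseline_df(FULL))
        assert s.pct_convex_by_level[4.6] == 100.0
        assert s.pct_convex_by_level[-2.3] == 25.0
        assert s.pct_convex_by_level[0.0] == 50.0
        assert s.n_by_level[0.0] == 40  # both zero-disparity conditions pooled
        assert not s.incomplete

    def test_incomplete_subject_flagged(self):
        partial = {k: v for k, v in FULL.items() if k != 2.3}
        s = summarize_subject(_baseline_df(partial))
        assert s.incomplete

    def test_depth_perception(self):
        assert depth_perception_score(summarize_subject(_baseline_df(FULL))) == 100.0
        flat = summarize_subject(_baseline_df({-4.6: (10, 20), 4.6: (10, 20)}))
        assert depth_perception_score(flat) == 0.0
        biased = summarize_subject(_baseline_df({-4.6: (4, 20), 4.6: (4, 20)}))
        assert depth_perception_score(biased) == 0.0
        missing = summarize_subject(_baseline_df({4.6: (10, 20)}))
        with pytest.raises(ValueError):
            depth_perception_score(missing)


class TestAnova:
    def test_df_match_group_sizes(self, rng):
        # 10 impaired subjects -> df (4, 45); 8 stereoscopic -> df (4, 35)
        for n_subj, df2 in ((10, 45), (8, 35)):
            data = {lv: rng.uniform(0, 100, n_subj) for lv in (-4.6, -2.3, 0.0, 2.3, 4.6)}
            res = one_way_anova(data)
            assert res.df == (4, df2)

    def test_matches_brute_force_and_scipy(self, rng):
        groups = {i: rng.normal(50 + 5 * i, 10, 9) for i in range(5)}
        res = one_way_anova(groups)
        vals = list(groups.values())
        f_scipy, p_scipy = stats.f_oneway(*vals)
        assert res.statistic == pytest.approx(float(f_scipy), abs=1e-10)
        assert res.p_value == pytest.approx(float(p_scipy), abs=1e-10)
        # explicit sums-of-squares oracle
        allv = np.concatenate(vals)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in vals)
        ss_between = ss_total - ss_within
        f_brute = (ss_between / 4) / (ss_within / (allv.size - 5))
        assert res.statistic == pytest.approx(f_brute, abs=1e-10)

    def test_two_level_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        res = one_way_anova({0: a, 1: b})
        t = stats.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t**2, abs=1e-10)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            one_way_anova({0: np.array([5.0, 5.0]), 1: np.array([5.0, 5.0])})


class TestTTests:
    def test_symmetric_values_give_zero(self):
        assert one_sample_t(np.array([40.0, 60.0])).statistic == pytest.approx(0.0)

    def test_df_and_formula_oracle(self, rng):
        v = rng.uniform(30, 90, 8)
        res = one_sample_t(v)
        assert res.df == 7
        t = (v.mean() - 50.0) / (v.std(ddof=1) / np.sqrt(v.size))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 7), abs=1e-12)

    @given(shift=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_location_equivariance(self, shift):
        v = np.array([42.0, 55.0, 61.0, 48.0])
        base = one_sample_t(v, mu=50.0).statistic
        shifted = one_sample_t(v + shift, mu=50.0 + shift).statistic
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            one_sample_t(np.array([50.0, 50.0]))

    def test_paired_equals_one_sample_on_differences(self, rng):
        a, b = rng.uniform(0, 100, 8), rng.uniform(0, 100, 8)
        res = paired_t(a, b)
        ref = one_sample_t(a - b, mu=0.0)
        assert res.df == 7
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-12)

    def test_paired_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t(a, a)


class TestLinearFit:
    def test_df_and_collinear(self):
        x = np.arange(8.0)
        fit = linear_fit(x, 0.1 * x + 0.2)
        assert fit["df"] == 6
        assert fit["r"] == pytest.approx(1.0)
        assert fit["sse"] == pytest.approx(0.0, abs=1e-12)

    def test_normal_equation_oracle(self, rng):
        x, y = rng.uniform(0, 100, 10), rng.uniform(0, 1, 10)
        fit = linear_fit(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit["slope"] == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        assert fit["sse"] == pytest.approx(float(resid @ resid), abs=1e-10)
        assert fit["r"] == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_constant_x_error(self):
        with pytest.raises(ValueError):
            linear_fit(np.ones(5), np.arange(5.0))


def test_group_analysis_qualitative_pattern():
    # stereoscopic-like subjects: strong far coupling, chance near coupling;
    # impaired-like subjects: neither above chance
    from stereocoupling.observers import (
        CouplingObserverParams,
        ObserverParams,
        SubjectSpec,
        simulate_cohort,
    )

    cohort = [
        SubjectSpec(f"st{i}", ObserverParams(0.0, 5.0),
                    CouplingObserverParams(g_far=0.9)) for i in range(8)
    ] + [
        SubjectSpec(f"im{i}", ObserverParams(0.0, 150.0),
                    CouplingObserverParams()) for i in range(10)
    ]
    df, _ = simulate_cohort(cohort, seed=44, repeats=20, coupling_trials_per_condition=40)
    groups = {f"st{i}": "stereoscopic" for i in range(8)}
    groups.update({f"im{i}": "stereovision-impaired" for i in range(10)})
    out = group_analysis(summarize_cohort(df), groups)
    st_g = out["groups"]["stereoscopic"]
    im_g = out["groups"]["stereovision-impaired"]
    assert st_g["anova_disparity"]["df"] == [4, 35]
    assert im_g["anova_disparity"]["df"] == [4, 45]
    assert st_g["coupling_far_vs_chance"]["p_value"] < 0.05
    assert st_g["coupling_far_vs_chance"]["statistic"] > 0
    # chance-level conditions: group mean within 3 binomial SEs of 50%
    se = 100 * 0.5 / np.sqrt(8 * 40)
    assert abs(st_g["mean_coupling"]["near"] - 50.0) < 3 * se
    se = 100 * 0.5 / np.sqrt(10 * 40)
    assert abs(im_g["mean_coupling"]["near"] - 50.0) < 3 * se
    assert abs(im_g["mean_coupling"]["far"] - 50.0) < 3 * se
    assert st_g["far_coupling_vs_depth_fit"]["df"] == 6
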