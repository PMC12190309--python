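"""Outlier fences, factorial ANOVA/ANCOVA vs brute-force oracles, permutation SPM."""

import numpy as np
import pandas as pd
import pytest

from gaitcoord.stats import iqr_exclude, spm_ttest2, two_way_anova, two_way_ancova


def _summary_df(values, group="HOA", speed="preferred", metric="marp_deg"):
    rows = []
    for i, v in enumerate(values):
        rows.append(
            {
                "participant": f"{group}{i:03d}",
                "group": group,
                "speed": speed,
                "marp_deg": 60.0,
                "dp_deg": 10.0,
                "hip_excursion_deg": 40.0,
                "knee_excursion_deg": 60.0,
                "walking_speed_mps": 1.0,
                "n_cycles": 10,
                metric: v,
            }
        )
    return pd.DataFrame(rows)


class TestIqrExclude:
    def test_hand_case_upper_fence(self):
        """{1,2,3,4,100}: Q1=2, Q3=4, upper fence 7 -> only 100 excluded."""
        df = _summary_df([1.0, 2.0, 3.0, 4.0, 100.0])
        retained, log = iqr_exclude(df, metrics=("marp_deg",))
        assert list(log["value"]) == [100.0]
        assert log["fence_hi"].iloc[0] == pytest.approx(7.0)
        assert len(retained) == 4

    def test_all_equal_none_excluded(self):
        df = _summary_df([5.0] * 6)
        retained, log = iqr_exclude(df, metrics=("marp_deg",))
        assert log.empty
        assert len(retained) == 6

    def test_planted_outliers_in_cohort(self):
        """48 participants, 5 planted extremes -> exactly those 5 excluded."""
        rng = np.random.default_rng(4)
        vals = list(rng.normal(60.0, 3.0, 43)) + [200.0, 210.0, -100.0, 250.0, -90.0]
        df = _summary_df(vals)
        retained, log = iqr_exclude(df, metrics=("marp_deg",))
        assert set(log["participant"]) == {f"HOA{i:03d}" for i in range(43, 48)}
        assert len(retained) == 43

    def test_exclusion_spans_all_conditions(self):
        pref = _summary_df([1.0, 2.0, 3.0, 4.0, 100.0])
        slow = pref.copy()
        slow["speed"] = "slow"
        slow["marp_deg"] = 50.0  # unremarkable at slow speed
        df = pd.concat([pref, slow], ignore_index=True)
        retained, _ = iqr_exclude(df, metrics=("marp_deg",))
        assert "HOA004" not in set(retained["participant"])

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            iqr_exclude(_summary_df([1.0, 2.0, 3.0]), metrics=("marp_deg",))


def _toy_design(seed=0, reps=2, shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("HOA", "PD"):
        for s in ("slow", "preferred", "fast"):
            for r in range(reps):
                rows.append(
                    {
                        "participant": f"{g}{s}{r}",
                        "group": g,
                        "speed": s,
                        "walking_speed_mps": rng.normal(1.0, 0.2),
                        "marp_deg": rng.normal(60.0 + (shift if g == "PD" else 0.0), 5.0),
                    }
                )
    return pd.DataFrame(rows)


def _sse(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _design_columns(df, covariate=None):
    """Dummy-coded columns for intercept, group, speed, interaction, covariate."""
    g = (df["group"] == "PD").to_numpy(float)
    s1 = (df["speed"] == "preferred").to_numpy(float)
    s2 = (df["speed"] == "slow").to_numpy(float)
    cols = {
        "intercept": np.ones(len(df)),
        "A": [g],
        "B": [s1, s2],
        "AB": [g * s1, g * s2],
    }
    if covariate:
        cols["cov"] = [df[covariate].to_numpy(float)]
    return cols


def _type2_f_oracle(df, response, covariate=None):
    """Brute-force type-II F statistics via least-squares model comparisons."""
    cols = _design_columns(df, covariate)
    y = df[response].to_numpy(float)

    def X(*terms):
        parts = [cols["intercept"][:, None]]
        for t in terms:
            parts.extend(np.asarray(c)[:, None] for c in cols[t])
        return np.hstack(parts)

    full_terms = ["A", "B", "AB"] + (["cov"] if covariate else [])
    X_full = X(*full_terms)
    sse_full = _sse(X_full, y)
    df_resid = len(y) - X_full.shape[1]
    mse = sse_full / df_resid

    out = {}
    comparisons = {
        "A": (["B"] + (["cov"] if covariate else []), ["A", "B"] + (["cov"] if covariate else [])),
        "B": (["A"] + (["cov"] if covariate else []), ["A", "B"] + (["cov"] if covariate else [])),
        "AB": (["A", "B"] + (["cov"] if covariate else []), full_terms),
    }
    if covariate:
        comparisons["cov"] = (["A", "B", "AB"], full_terms)
    for term, (reduced, fuller) in comparisons.items():
        ss = _sse(X(*reduced), y) - _sse(X(*fuller), y)
        df_num = len(cols[term])
        out[term] = ss / df_num / mse
    return out


class TestTwoWayAnova:
    def test_matches_brute_force_type2_oracle(self):
        df = _toy_design(seed=1)
        rep = two_way_anova(df, "walking_speed_mps")
        oracle = _type2_f_oracle(df, "walking_speed_mps")
        assert rep.effect("group").F == pytest.approx(oracle["A"], abs=1e-10)
        assert rep.effect("speed").F == pytest.approx(oracle["B"], abs=1e-10)
        assert rep.effect("group:speed").F == pytest.approx(oracle["AB"], abs=1e-10)

    def test_planted_group_shift_detected_with_posthoc(self):
        df = _toy_design(seed=2, reps=20, shift=10.0)
        rep = two_way_anova(df, "marp_deg")
        assert rep.effect("group").p < 0.05
        assert (rep.posthoc["factor"] == "group").any()
        row = rep.posthoc[rep.posthoc["factor"] == "group"].iloc[0]
        assert row["p_bonferroni"] <= 1.0

    def test_empty_cell_named(self):
        df = _toy_design(seed=3)
        df = df[~((df["group"] == "PD") & (df["speed"] == "slow"))]
        with pytest.raises(ValueError, match="group=PD, speed=slow"):
            two_way_anova(df, "walking_speed_mps")


class TestTwoWayAncova:
    def test_matches_least_squares_oracle_12_rows(self):
        df = _toy_design(seed=5, reps=2)
        assert len(df) == 12
        rep = two_way_ancova(df, "marp_deg", covariate="walking_speed_mps")
        oracle = _type2_f_oracle(df, "marp_deg", covariate="walking_speed_mps")
        assert rep.effect("group").F == pytest.approx(oracle["A"], abs=1e-8)
        assert rep.effect("speed").F == pytest.approx(oracle["B"], abs=1e-8)
        assert rep.effect("group:speed").F == pytest.approx(oracle["AB"], abs=1e-8)
        assert rep.effect("covariate").F == pytest.approx(oracle["cov"], abs=1e-8)

    def test_response_equal_covariate_is_pure_covariate_effect(self):
        """Perfect confound: the covariate absorbs everything; factor sums of
        squares collapse to float noise many orders below the covariate's."""
        df = _toy_design(seed=6, reps=4)
        df["marp_deg"] = df["walking_speed_mps"]
        rep = two_way_ancova(df, "marp_deg", covariate="walking_speed_mps")
        assert rep.effect("covariate").F > 1e10 * rep.effect("group").F
        assert rep.effect("covariate").partial_eta2 == pytest.approx(1.0, abs=1e-9)

    def test_partial_eta2_in_unit_interval(self):
        rep = two_way_ancova(_toy_design(seed=7, reps=5), "marp_deg")
        for e in rep.effects:
            assert 0.0 <= e.partial_eta2 <= 1.0

    def test_zero_variance_covariate_rejected(self):
        df = _toy_design(seed=8)
        df["walking_speed_mps"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            two_way_ancova(df, "marp_deg")

    def test_interaction_gating_no_posthoc_under_null(self):
        rep = two_way_ancova(_toy_design(seed=9, reps=10), "marp_deg")
        if rep.effect("group:speed").p >= rep.alpha:
            assert rep.posthoc.empty


class TestSpmTtest2:
    def test_constant_waveforms_match_hand_t(self):
        """Constant curves reduce every node to a scalar two-sample t."""
        from scipy.stats import ttest_ind

        a_vals, b_vals = [10.0, 12.0, 11.0], [14.0, 15.0, 16.0]
        a = np.tile(np.array(a_vals)[:, None], (1, 101))
        b = np.tile(np.array(b_vals)[:, None], (1, 101))
        res = spm_ttest2(a, b, n_perm=100, rng=np.random.default_rng(0))
        t_hand = ttest_ind(a_vals, b_vals).statistic
        np.testing.assert_allclose(res.t, t_hand, atol=1e-10)

    def test_planted_effect_cluster_overlaps(self):
        rng = np.random.default_rng(10)
        base = np.sin(np.linspace(0, np.pi, 101)) * 10.0
        a = base + rng.normal(0, 1.0, (10, 101))
        b = base + rng.normal(0, 1.0, (10, 101))
        b[:, 40:61] += 3.0  # 3-SD shift on nodes 40-60
        res = spm_ttest2(a, b, n_perm=500, rng=rng)
        assert res.clusters, "expected a supra-threshold cluster"
        assert any(s <= 60 and e >= 40 for s, e in res.clusters)

    def test_threshold_monotone_in_alpha(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1.0, (8, 101))
        b = rng.normal(0, 1.0, (8, 101))
        ts = [
            spm_ttest2(a, b, alpha=al, n_perm=400, rng=np.random.default_rng(5)).t_star
            for al in (0.01, 0.05, 0.2)
        ]
        assert ts[0] >= ts[1] >= ts[2]

    def test_deterministic_under_fixed_seed(self):
        rng_data = np.random.default_rng(12)
        a = rng_data.normal(size=(6, 101))
        b = rng_data.normal(size=(6, 101))
        r1 = spm_ttest2(a, b, n_perm=200, rng=np.random.default_rng(3))
        r2 = spm_ttest2(a, b, n_perm=200, rng=np.random.default_rng(3))
        assert r1.t_star == r2.t_star
        np.testing.assert_array_equal(r1.t, r2.t)

    def test_zero_variance_node_finite(self):
        a = np.zeros((4, 101))
        b = np.ones((4, 101))
        a[:, :50] = np.random.default_rng(6).normal(size=(4, 50))
        b[:, :50] = np.random.default_rng(7).normal(size=(4, 50))
        res = spm_ttest2(a, b, n_perm=120, rng=np.random.default_rng(8))
        assert np.all(np.isfinite(res.t))

    def test_too_few_waveforms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spm_ttest2(np.zeros((2, 101)), np.zeros((5, 101)))
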