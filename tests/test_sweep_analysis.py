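import numpy as np
import pytest

from connethresh.sweep_analysis import (AnalysisError,
                                        baseline_followup_correlation,
                                        cohort_metric_table,
                                        cross_threshold_correlation,
                                        longitudinal_zscores, median_split,
                                        mixed_anova, sensitivity_sweep)
from connethresh.synth import GeneratorConfig, generate_cohort


def mixed_anova_ss_oracle(b, f, groups):
    """Brute-force split-plot sums of squares for a *balanced* design."""
    b, f = np.asarray(b, float), np.asarray(f, float)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    y = {}  # (subject, time) -> value
    n = len(b)
    for s in range(n):
        y[(s, 0)] = b[s]
        y[(s, 1)] = f[s]
    grand = np.mean(list(y.values()))
    subj_mean = {s: (b[s] + f[s]) / 2 for s in range(n)}
    grp_mean = {lab: np.mean([subj_mean[s] for s in range(n) if g[s] == lab])
                for lab in labels}
    time_mean = {0: b.mean(), 1: f.mean()}
    cell_mean = {(lab, t): np.mean([y[(s, t)] for s in range(n)
                                    if g[s] == lab])
                 for lab in labels for t in (0, 1)}
    n_g = {lab: int((g == lab).sum()) for lab in labels}

    ss_between = 2 * sum((subj_mean[s] - grand) ** 2 for s in range(n))
    ss_group = sum(2 * n_g[lab] * (grp_mean[lab] - grand) ** 2
                   for lab in labels)
    ss_subj_within = ss_between - ss_group
    ss_time = sum(n * (time_mean[t] - grand) ** 2 for t in (0, 1))
    ss_int = sum(n_g[lab] * (cell_mean[(lab, t)] - grp_mean[lab]
                             - time_mean[t] + grand) ** 2
                 for lab in labels for t in (0, 1))
    ss_total = sum((v - grand) ** 2 for v in y.values())
    ss_err_within = ss_total - ss_between - ss_time - ss_int
    ms_err_b = ss_subj_within / (n - 2)
    ms_err_w = ss_err_within / (n - 2)
    return {"time": ss_time / ms_err_w, "group": ss_group / ms_err_b,
            "interaction": ss_int / ms_err_w}


class TestLongitudinalZScores:
    def test_hand_computed_sample_sd(self):
        z = longitudinal_zscores(np.array([[1.0], [2.0], [3.0]]),
                                 np.array([[2.0], [2.0], [2.0]]))
        np.testing.assert_allclose(z.z_baseline[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(z.z_followup[:, 0], [0.0, 0.0, 0.0])

    def test_followup_identical_change_zero(self, rng):
        x = rng.normal(size=(6, 4))
        z = longitudinal_zscores(x, x)
        np.testing.assert_allclose(z.change, 0.0, atol=1e-12)

    def test_standardization_invariant(self, rng):
        x = rng.normal(3.0, 2.0, size=(20, 5))
        z = longitudinal_zscores(x, x + 1)
        np.testing.assert_allclose(z.z_baseline.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.z_baseline.std(axis=0, ddof=1), 1.0,
                                   atol=1e-10)

    def test_constant_followup_shift_in_sd_units(self, rng):
        x = rng.normal(size=(10, 3))
        z0 = longitudinal_zscores(x, x)
        z1 = longitudinal_zscores(x, x + 0.5)
        sd = x.std(axis=0, ddof=1)
        np.testing.assert_allclose(z0.change - z1.change,
                                   np.broadcast_to(0.5 / sd, (10, 3)),
                                   atol=1e-10)

    def test_zero_baseline_sd_flagged(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        z = longitudinal_zscores(x, x, levels=[0.1, 0.2])
        assert z.degenerate_levels == (0.1,)
        assert np.isnan(z.z_baseline[:, 0]).all()


class TestCrossThresholdCorrelation:
    def test_copied_column_r_one(self, rng):
        a = rng.normal(size=10)
        r = cross_threshold_correlation(np.column_stack([a, a])).r_matrix
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self, rng):
        a = rng.normal(size=10)
        r = cross_threshold_correlation(np.column_stack([a, -a])).r_matrix
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(500, 2))
        r = cross_threshold_correlation(x).r_matrix
        assert abs(r[0, 1]) < 0.1

    def test_symmetric_unit_diagonal(self, rng):
        x = rng.normal(size=(15, 6))
        r = cross_threshold_correlation(x).r_matrix
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.nanmax(np.abs(r)) <= 1 + 1e-12


class TestBaselineFollowupCorrelation:
    def test_identical_r_one(self, rng):
        x = rng.normal(size=(12, 3))
        z = longitudinal_zscores(x, x)
        np.testing.assert_allclose(baseline_followup_correlation(z), 1.0,
                                   atol=1e-12)

    def test_equal_noise_attenuation(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(4000, 1))
        follow = base + rng.normal(size=(4000, 1))
        z = longitudinal_zscores(base, follow)
        r = baseline_followup_correlation(z)[0]
        assert r == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(10)
        z = longitudinal_zscores(rng.normal(size=(2000, 1)),
                                 rng.normal(size=(2000, 1)))
        assert abs(baseline_followup_correlation(z)[0]) < 0.06


class TestMedianSplit:
    def test_even_split(self):
        got = median_split({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert got == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_odd_median_goes_low(self):
        got = median_split({"a": 1.0, "b": 2.0, "c": 3.0})
        assert got["b"] == "low"
        assert got == {"a": "low", "b": "low", "c": "high"}

    def test_missing_excluded(self):
        got = median_split({"a": 1.0, "b": float("nan"), "c": 3.0})
        assert "b" not in got and len(got) == 2

    def test_all_equal_error(self):
        with pytest.raises(AnalysisError, match="undefined"):
            median_split({"a": 2.0, "b": 2.0, "c": 2.0})

    def test_too_few_error(self):
        with pytest.raises(AnalysisError):
            median_split({"a": 1.0})


class TestMixedAnova:
    def test_no_effects_all_f_zero(self):
        b = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = ["low"] * 3 + ["high"] * 3
        res = mixed_anova(b, b.copy(), g)
        for eff in ("time", "group", "interaction"):
            assert res[eff].F == pytest.approx(0.0, abs=1e-12)
            assert res[eff].df == (1, 4)

    def test_balanced_matches_ss_oracle(self, rng):
        n = 12
        g = np.array(["low"] * 6 + ["high"] * 6)
        b = rng.normal(0, 1, n) + (g == "high") * 0.8
        f = b + rng.normal(0.4, 0.3, n) + (g == "high") * 0.3
        res = mixed_anova(b, f, g)
        oracle = mixed_anova_ss_oracle(b, f, g)
        for eff in ("time", "group", "interaction"):
            assert res[eff].F == pytest.approx(oracle[eff], abs=1e-8)

    def test_balanced_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        n = 16
        g = np.array(["low"] * 8 + ["high"] * 8)
        b = rng.normal(0, 1, n)
        f = b + rng.normal(0.2, 0.5, n) + (g == "high") * 0.4
        res = mixed_anova(b, f, g)
        df = pd.DataFrame({"y": np.r_[b, f], "time": ["b"] * n + ["f"] * n,
                           "grp": np.r_[g, g],
                           "subj": np.r_[np.arange(n), np.arange(n)]})
        aov = pg.mixed_anova(df, dv="y", within="time", between="grp",
                             subject="subj").set_index("Source")
        assert res["group"].F == pytest.approx(aov.loc["grp", "F"], rel=1e-9)
        assert res["time"].F == pytest.approx(aov.loc["time", "F"], rel=1e-9)
        assert res["interaction"].F == pytest.approx(
            aov.loc["Interaction", "F"], rel=1e-9)

    def test_pure_time_effect(self, rng):
        n = 40
        g = np.array(["low"] * 20 + ["high"] * 20)
        b = rng.normal(0, 1, n)
        f = b - 0.8 + rng.normal(0, 0.1, n)
        res = mixed_anova(b, f, g)
        assert res["time"].p < 1e-6
        assert res["group"].p > 0.01
        assert res["time"].cohens_d > 0  # decline: baseline minus follow-up

    def test_small_group_error(self):
        with pytest.raises(AnalysisError, match=">= 3"):
            mixed_anova([1, 2, 3, 4.0], [1, 2, 3, 4.0],
                        ["low", "low", "low", "high"])

    def test_one_group_error(self):
        with pytest.raises(AnalysisError, match="2 groups"):
            mixed_anova([1, 2, 3.0], [1, 2, 3.0], ["low"] * 3)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = GeneratorConfig(n_nodes=30, n_subjects=12, seed=5)
    cohort, _ = generate_cohort(cfg)
    return cohort


class TestSensitivitySweep:
    def test_identity_cohort_null_f(self):
        cfg = GeneratorConfig(n_nodes=24, n_subjects=8, seed=2).noise_free()
        cohort, _ = generate_cohort(cfg)
        tab = sensitivity_sweep(cohort, "mean_strength_FA", "fixed_density",
                                levels=[0.1, 0.2])
        assert (tab["F_time"] < 1e-10).all()

    def test_table_shape_and_critical_f(self, small_cohort):
        levels = [0.1, 0.15, 0.2]
        tab = sensitivity_sweep(small_cohort, "global_efficiency",
                                "fixed_density", levels)
        assert len(tab) == 3
        assert {"F_time", "p_group", "d_interaction",
                "critical_F"} <= set(tab.columns)
        from scipy import stats
        np.testing.assert_allclose(tab["critical_F"],
                                   stats.f.isf(0.05, 1, tab["df_den"]))

    def test_deterministic(self, small_cohort):
        levels = [0.1, 0.2]
        t1 = sensitivity_sweep(small_cohort, "mean_strength_MD",
                               "fixed_density", levels)
        t2 = sensitivity_sweep(small_cohort, "mean_strength_MD",
                               "fixed_density", levels)
        assert t1.equals(t2)

    def test_cohort_metric_table_shapes(self, small_cohort):
        lv, xb, xf, ids = cohort_metric_table(small_cohort,
                                              "mean_strength_FA",
                                              "fixed_density", [0.1, 0.2])
        assert xb.shape == (12, 2) and xf.shape == (12, 2)
        assert list(lv) == [0.1, 0.2]
        assert len(ids) == 12
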