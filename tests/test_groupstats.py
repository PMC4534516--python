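"""ANOVA partitioning, linear contrast, Dunnett adjustment, report tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from progratio import analyze_experiment, dunnett, mixed_anova_2x2, rm_anova_dose
from progratio.errors import ArgumentError, DesignError
from progratio.groupstats import group_summary


def _long(values, groups, conditions):
    """values[g][s][c] → long-format frame."""
    rows = []
    for gi, g in enumerate(groups):
        for si, subj in enumerate(values[gi]):
            for ci, v in enumerate(subj):
                rows.append(
                    {"rat_id": f"{g}_r{si}", "group": g, "condition": conditions[ci], "value": v}
                )
    return pd.DataFrame(rows)


def _random_mixed_frame(rng, n1=5, n2=5, C=2):
    vals = [rng.normal(10, 3, size=(n1, C)), rng.normal(12, 3, size=(n2, C))]
    return _long(vals, ["g1", "g2"], [f"c{i}" for i in range(C)])


class TestMixedAnova:
    def test_matches_pingouin_on_balanced_fixture(self, rng):
        pg = pytest.importorskip("pingouin")
        data = _random_mixed_frame(rng)
        ours = mixed_anova_2x2(data).set_index("effect")
        theirs = pg.mixed_anova(
            data=data, dv="value", within="condition", subject="rat_id", between="group"
        ).set_index("Source")
        for mine, pg_name in [("group", "group"), ("condition", "condition"),
                              ("group*condition", "Interaction")]:
            assert ours.loc[mine, "F"] == pytest.approx(theirs.loc[pg_name, "F"], rel=1e-8)
            assert ours.loc[mine, "p"] == pytest.approx(theirs.loc[pg_name, "p_unc"], rel=1e-8)
            assert ours.loc[mine, "eta_p2"] == pytest.approx(theirs.loc[pg_name, "np2"], rel=1e-6)

    def test_matches_explicit_partition_on_integer_fixture(self):
        """Hand-checkable 2 groups × 2 conditions × 4 rats fixture against a
        from-scratch cell-means partition."""
        vals = [
            [[3, 5], [4, 6], [5, 9], [4, 8]],
            [[7, 6], [8, 8], [9, 7], [8, 9]],
        ]
        data = _long(vals, ["g1", "g2"], ["c1", "c2"])
        table = mixed_anova_2x2(data).set_index("effect")

        Y = np.array(vals, dtype=float)  # (G, S, C)
        grand = Y.mean()
        subj = Y.mean(axis=2)
        grp = Y.mean(axis=(1, 2))
        cond_in_grp = Y.mean(axis=1)
        C, S = 2, 4
        ss_g = C * S * ((grp - grand) ** 2).sum()
        ss_subj = C * ((subj - grp[:, None]) ** 2).sum()
        b_c = cond_in_grp.mean(axis=0) - grand
        ss_c = 2 * S * (b_c**2).sum()
        ss_i = S * ((cond_in_grp - cond_in_grp.mean(axis=1, keepdims=True) - b_c) ** 2).sum()
        resid = Y - subj[:, :, None] - cond_in_grp[:, None, :] + grp[:, None, None]
        ss_e = (resid**2).sum()
        assert table.loc["group", "ss"] == pytest.approx(ss_g)
        assert table.loc["condition", "ss"] == pytest.approx(ss_c)
        assert table.loc["group*condition", "ss"] == pytest.approx(ss_i)
        assert table.loc["residual", "ss"] == pytest.approx(ss_e)
        f_within = (ss_c / 1) / (ss_e / 6)
        assert table.loc["condition", "F"] == pytest.approx(f_within)
        assert table.loc["condition", "df1"] == 1
        assert table.loc["condition", "df2"] == 6

    def test_identical_within_values_give_zero_condition_effect(self):
        vals = [[[4, 4], [6, 6], [5, 5]], [[7, 7], [9, 9], [8, 8]]]
        table = mixed_anova_2x2(_long(vals, ["g1", "g2"], ["c1", "c2"])).set_index("effect")
        assert table.loc["condition", "F"] == 0.0
        assert table.loc["condition", "eta_p2"] == 0.0

    def test_partitions_sum_to_total(self, rng):
        data = _random_mixed_frame(rng, n1=6, n2=4, C=3)
        t = mixed_anova_2x2(data).set_index("effect")
        parts = (
            t.loc["group", "ss"] + t.loc["subjects(group)", "ss"] + t.loc["condition", "ss"]
            + t.loc["group*condition", "ss"] + t.loc["residual", "ss"]
        )
        assert parts == pytest.approx(t.loc["total", "ss"], rel=1e-10)

    def test_eta_p2_half_when_effect_equals_error(self):
        # condition effect ±1 around subject mean, residual ±1 as well:
        # construct directly from the definition instead
        vals = [[[0, 2], [1, 3]], [[0, 2], [3, 1]]]
        t = mixed_anova_2x2(_long(vals, ["g1", "g2"], ["c1", "c2"])).set_index("effect")
        ss, ss_err = t.loc["condition", "ss"], t.loc["residual", "ss"]
        assert t.loc["condition", "eta_p2"] == pytest.approx(ss / (ss + ss_err))

    def test_eta_p2_invariant_to_affine_transform(self, rng):
        data = _random_mixed_frame(rng)
        t1 = mixed_anova_2x2(data).set_index("effect")
        data2 = data.assign(value=3.5 * data["value"] - 11.0)
        t2 = mixed_anova_2x2(data2).set_index("effect")
        for eff in ("group", "condition", "group*condition"):
            assert t1.loc[eff, "eta_p2"] == pytest.approx(t2.loc[eff, "eta_p2"], rel=1e-9)

    def test_listwise_deletion_of_incomplete_subjects(self, rng):
        data = _random_mixed_frame(rng)
        dropped = data[~((data["rat_id"] == "g1_r0") & (data["condition"] == "c1"))]
        full = mixed_anova_2x2(data[data["rat_id"] != "g1_r0"]).set_index("effect")
        auto = mixed_anova_2x2(dropped).set_index("effect")
        assert auto.loc["condition", "F"] == pytest.approx(full.loc["condition", "F"])

    def test_too_small_group_rejected(self):
        vals = [[[1, 2]], [[3, 4], [5, 6]]]
        with pytest.raises(DesignError):
            mixed_anova_2x2(_long(vals, ["g1", "g2"], ["c1", "c2"]))


def _dose_frame(Y, levels=("vehicle", "0.3", "1", "3")):
    rows = []
    for si, subj in enumerate(Y):
        for ci, v in enumerate(subj):
            rows.append({"rat_id": f"r{si}", "condition": levels[ci], "value": v})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_pingouin_on_random_fixture(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(20, 5, size=(8, 4))
        data = _dose_frame(Y)
        table, _ = rm_anova_dose(data, order=["vehicle", "0.3", "1", "3"])
        theirs = pg.rm_anova(
            data=data, dv="value", within="condition", subject="rat_id",
            detailed=True, effsize="np2",
        ).set_index("Source")
        mine = table.set_index("effect")
        assert mine.loc["condition", "F"] == pytest.approx(theirs.loc["condition", "F"], rel=1e-8)
        assert mine.loc["condition", "p"] == pytest.approx(
            theirs.loc["condition", "p_unc"], rel=1e-8
        )
        assert mine.loc["condition", "eta_p2"] == pytest.approx(
            theirs.loc["condition", "np2"], rel=1e-6
        )

    def test_constant_series_gives_zero_fs(self):
        Y = np.tile([[5.0], [7.0], [9.0]], (1, 4))
        table, contrast = rm_anova_dose(_dose_frame(Y))
        assert table.set_index("effect").loc["condition", "F"] == 0.0
        assert contrast["F"] == 0.0

    def test_linear_trend_captures_all_treatment_ss(self, rng):
        base = rng.normal(10, 2, size=8)
        Y = base[:, None] + 2.0 * np.arange(4)[None, :]
        table, contrast = rm_anova_dose(_dose_frame(Y))
        ss_treat = table.set_index("effect").loc["condition", "ss"]
        assert contrast["ss"] == pytest.approx(ss_treat, rel=1e-10)

    def test_contrast_f_is_squared_one_sample_t_of_scores(self, rng):
        Y = rng.normal(10, 2, size=(6, 4))
        _, contrast = rm_anova_dose(_dose_frame(Y))
        coef = contrast["coefficients"]
        scores = Y @ coef
        t, _ = stats.ttest_1samp(scores, 0.0)
        assert contrast["F"] == pytest.approx(t**2, rel=1e-10)
        assert contrast["df2"] == 5

    def test_incomplete_series_rejected(self, rng):
        data = _dose_frame(rng.normal(size=(4, 4)))
        with pytest.raises(DesignError):
            rm_anova_dose(data[~((data["rat_id"] == "r0") & (data["condition"] == "1"))])

    def test_log_coding_requires_positive_numeric_doses(self, rng):
        data = _dose_frame(rng.normal(size=(4, 4)))
        with pytest.raises(ArgumentError):
            rm_anova_dose(data, contrast_coding="log")  # "vehicle" is not numeric


class TestDunnett:
    def test_identical_groups_never_rejected(self):
        Y = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))
        res = dunnett(_dose_frame(Y), control="vehicle")
        assert not res["reject"].any()
        assert (res["p_adjusted"] > 0.9).all()

    def test_single_comparison_reduces_to_paired_t(self, rng):
        Y = rng.normal(10, 2, size=(8, 2))
        data = _dose_frame(Y, levels=("vehicle", "1"))
        res = dunnett(data, control="vehicle")
        t, p = stats.ttest_rel(Y[:, 1], Y[:, 0])
        assert res["t"].iloc[0] == pytest.approx(t, rel=1e-9)
        assert res["p_adjusted"].iloc[0] == pytest.approx(p, rel=1e-4)
        assert res["p_unadjusted"].iloc[0] == pytest.approx(p, rel=1e-9)

    def test_adjusted_p_never_below_unadjusted(self, rng):
        Y = rng.normal(10, 2, size=(10, 4))
        Y[:, 2] += 2.0
        res = dunnett(_dose_frame(Y), control="vehicle")
        assert (res["p_adjusted"] >= res["p_unadjusted"] - 1e-12).all()

    def test_large_true_effect_detected(self, rng):
        Y = rng.normal(10, 1, size=(10, 4))
        Y[:, 3] += 6.0
        res = dunnett(_dose_frame(Y), control="vehicle").set_index("level")
        assert bool(res.loc["3", "reject"])

    def test_missing_control_label_rejected(self, rng):
        with pytest.raises(ArgumentError):
            dunnett(_dose_frame(rng.normal(size=(4, 4))), control="placebo")


class TestAnalyzeExperiment:
    def _params_frame(self, rng, effect_on_a=0.4):
        rows = []
        for g, a0 in [("sucrose", 23.4), ("corn_oil", 70.2)]:
            for i in range(6):
                base_a = a0 * rng.lognormal(0, 0.2)
                for cond, mult in [("deprived", 1.0), ("free_feeding", effect_on_a)]:
                    rows.append(
                        {
                            "rat_id": f"{g}_r{i}", "group": g, "condition": cond,
                            "t0": 3.0 * rng.lognormal(0, 0.1),
                            "k": 0.5 * rng.lognormal(0, 0.1),
                            "a": base_a * mult,
                            "delta": 0.2 * rng.lognormal(0, 0.1),
                        }
                    )
        return pd.DataFrame(rows)

    def test_deprivation_report_structure_and_detection(self, rng):
        params = self._params_frame(rng)
        report = analyze_experiment(params, design="deprivation")
        anova = report["anova"]
        a_cond = anova[(anova["measure"] == "a") & (anova["effect"] == "condition")]
        assert a_cond["p"].iloc[0] < 0.05
        assert set(report["summary"]["measure"]) == {"t0", "k", "a", "delta"}

    def test_posthocs_gated_on_significant_interaction(self, rng):
        params = self._params_frame(rng, effect_on_a=1.0)  # no within effect on a
        report = analyze_experiment(params, design="deprivation")
        anova = report["anova"].set_index(["measure", "effect"])
        posthoc_measures = set(report["posthoc"]["measure"]) if len(report["posthoc"]) else set()
        for m in ("t0", "k", "a", "delta"):
            significant = anova.loc[(m, "group*condition"), "p"] < 0.05
            assert (m in posthoc_measures) == significant

    def test_sem_equals_sd_over_sqrt_n(self):
        df = pd.DataFrame(
            {
                "group": "g", "condition": "c", "value": [1.0, 2.0, 6.0],
            }
        )
        summary = group_summary(df, ["value"])
        expected = np.std([1.0, 2.0, 6.0], ddof=1) / np.sqrt(3)
        assert summary["sem"].iloc[0] == pytest.approx(expected)

    def test_breakpoints_averaged_per_rat_and_analyzed(self, rng):
        params = self._params_frame(rng)
        bps = []
        for _, r in params.iterrows():
            for s in range(3):
                bps.append(
                    {
                        "rat_id": r["rat_id"], "group": r["group"],
                        "condition": r["condition"], "session_id": f"s{s}",
                        "breakpoint": 95 if r["condition"] == "deprived" else 40,
                    }
                )
        report = analyze_experiment(params, breakpoints=pd.DataFrame(bps))
        anova = report["anova"]
        bp_row = anova[(anova["measure"] == "breakpoint") & (anova["effect"] == "condition")]
        assert bp_row["p"].iloc[0] < 1e-6

    def test_dose_design_runs_contrast_and_dunnett(self, rng):
        rows = []
        for i in range(8):
            base = 20 * rng.lognormal(0, 0.15)
            for j, cond in enumerate(["vehicle", "0.3", "1", "3"]):
                rows.append(
                    {
                        "rat_id": f"r{i}", "group": "sucrose", "condition": cond,
                        "t0": 3.0, "k": 0.5, "a": base * (1 + 0.25 * j), "delta": 0.2,
                    }
                )
        params = pd.DataFrame(rows)
        report = analyze_experiment(
            params, design="dose", dose_order=["vehicle", "0.3", "1", "3"]
        )
        anova = report["anova"]
        assert "linear_contrast" in set(anova["effect"])
        lin = anova[(anova["measure"] == "a") & (anova["effect"] == "linear_contrast")]
        assert lin["p"].iloc[0] < 0.05
        assert not report["posthoc"].empty
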