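"""Tests for the cohort statistics, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tempovar.stats import (
    delta_correlation,
    render_table2,
    render_table3,
    rm_anova_per_region,
    tukey_posthoc,
    two_sample_t_per_region,
)

STAGES = ("acute", "subacute", "early_chronic")


def cohort_from_arrays(patients, controls=None, regions=("A", "B"), scores=None):
    """Build a long cohort table.

    ``patients``: dict region -> (n_subjects x n_stages) array.
    ``controls``: dict region -> (n_subjects,) array (baseline session).
    """
    rows = []
    for region, data in patients.items():
        data = np.asarray(data)
        for i in range(data.shape[0]):
            sid = f"P{i + 1:02d}"
            for j in range(data.shape[1]):
                rows.append(
                    dict(
                        subject_id=sid, group="patient", stage=STAGES[j],
                        region=region, V_mean=data[i, j],
                        score=scores[i][j] if scores is not None else np.nan,
                    )
                )
    if controls is not None:
        for region, data in controls.items():
            for i, v in enumerate(np.asarray(data)):
                rows.append(
                    dict(
                        subject_id=f"C{i + 1:02d}", group="control",
                        stage="baseline", region=region, V_mean=v, score=np.nan,
                    )
                )
    return pd.DataFrame(rows)


class TestTwoSampleT:
    def test_identical_groups_give_zero(self):
        v = np.array([0.5, 0.6, 0.7])
        tab = cohort_from_arrays({"A": v[:, None]}, {"A": v}, regions=("A",))
        res = two_sample_t_per_region(tab, "acute")
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # hand-computed: A={1,2,3}, B={2,3,4}; pooled sd=1,
        # t = (2-3)/sqrt(1*(1/3+1/3)) = -sqrt(3/2), df=4
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        tab = cohort_from_arrays({"A": a[:, None]}, {"A": b})
        res = two_sample_t_per_region(tab, "acute")
        t_hand = -np.sqrt(1.5)
        p_hand = 2 * sps.t.sf(np.sqrt(1.5), df=4)
        assert res.statistic[0] == pytest.approx(t_hand, abs=1e-10)
        assert res.p_value[0] == pytest.approx(p_hand, abs=1e-10)

    def test_sign_convention_patients_lower_is_negative(self, rng):
        pat = rng.normal(0.4, 0.01, size=10)
        con = rng.normal(0.8, 0.01, size=10)
        tab = cohort_from_arrays({"A": pat[:, None]}, {"A": con})
        res = two_sample_t_per_region(tab, "acute", alpha=0.005)
        assert res.statistic[0] < 0
        assert bool(res.significant[0])

    def test_welch_flag(self, rng):
        pat = rng.normal(0.4, 0.30, size=8)
        con = rng.normal(0.5, 0.01, size=20)
        tab = cohort_from_arrays({"A": pat[:, None]}, {"A": con})
        pooled = two_sample_t_per_region(tab, "acute")
        welch = two_sample_t_per_region(tab, "acute", equal_var=False)
        assert pooled.p_value[0] != welch.p_value[0]

    def test_empty_group_errors(self):
        tab = cohort_from_arrays({"A": np.array([[0.1], [0.2]])})
        with pytest.raises(ValueError, match="control"):
            two_sample_t_per_region(tab, "acute")


class TestRmAnova:
    def test_pure_subject_offsets_give_zero_f(self):
        offsets = np.array([0.2, 0.5, 0.9, 1.4])
        data = np.tile(offsets[:, None], (1, 3))
        tab = cohort_from_arrays({"A": data})
        res = rm_anova_per_region(tab, STAGES)
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_stage_f_equals_squared_paired_t(self, rng):
        for _ in range(20):
            data = rng.normal(size=(10, 2))
            tab = cohort_from_arrays({"A": data[:, :2]})
            res = rm_anova_per_region(tab, STAGES[:2])
            t, p = sps.ttest_rel(data[:, 1], data[:, 0])
            assert res.statistic[0] == pytest.approx(t**2, abs=1e-10)
            assert res.p_value[0] == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        data = rng.normal(size=(8, 3)) + np.array([0.0, 0.3, 0.1])
        tab = cohort_from_arrays({"A": data})
        res = rm_anova_per_region(tab, STAGES)
        long = tab[tab.group == "patient"]
        sm = AnovaRM(long, depvar="V_mean", subject="subject_id", within=["stage"]).fit()
        assert res.statistic[0] == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0]), abs=1e-10
        )
        assert res.p_value[0] == pytest.approx(
            float(sm.anova_table["Pr > F"].iloc[0]), abs=1e-10
        )

    def test_missing_cell_named(self):
        tab = cohort_from_arrays({"A": np.random.default_rng(0).normal(size=(4, 3))})
        tab = tab.drop(tab[(tab.subject_id == "P02") & (tab.stage == "subacute")].index)
        with pytest.raises(ValueError, match="P02"):
            rm_anova_per_region(tab, STAGES)

    def test_controls_never_enter(self, rng):
        data = rng.normal(size=(6, 3))
        with_controls = cohort_from_arrays({"A": data}, {"A": rng.normal(10, 1, 6)})
        without = cohort_from_arrays({"A": data})
        a = rm_anova_per_region(with_controls, STAGES)
        b = rm_anova_per_region(without, STAGES)
        assert a.statistic[0] == b.statistic[0]


class TestTukey:
    def test_equal_stage_means_not_significant(self, rng):
        data = rng.normal(size=(12, 3))
        data = data - data.mean(axis=0)  # stage means exactly equal
        tab = cohort_from_arrays({"A": data})
        res = tukey_posthoc(tab, "A", STAGES)
        assert (res.p_value > 0.999).all()
        assert np.allclose(res.statistic, 0.0, atol=1e-12)

    def test_single_shifted_stage_drives_its_two_pairs(self, rng):
        data = rng.normal(0, 0.01, size=(12, 3))
        data[:, 1] += 1.0  # only the subacute stage shifted
        tab = cohort_from_arrays({"A": data})
        res = tukey_posthoc(tab, "A", STAGES).set_index("comparison")
        assert res.loc["subacute_vs_acute"].significant
        assert res.loc["early_chronic_vs_subacute"].significant
        assert not res.loc["early_chronic_vs_acute"].significant

    def test_mean_diff_orientation_and_antisymmetry(self, rng):
        data = rng.normal(size=(8, 3))
        tab = cohort_from_arrays({"A": data})
        res = tukey_posthoc(tab, "A", STAGES).set_index("comparison")
        d21 = data[:, 1].mean() - data[:, 0].mean()
        assert res.loc["subacute_vs_acute"].statistic == pytest.approx(d21, abs=1e-12)
        rev = tukey_posthoc(tab, "A", ("subacute", "acute")).set_index("comparison")
        assert rev.loc["acute_vs_subacute"].statistic == pytest.approx(-d21, abs=1e-12)

    def test_studentized_range_p_from_rm_error_term(self, rng):
        # independent recomputation of the Tukey p for one pair
        data = rng.normal(size=(9, 3))
        tab = cohort_from_arrays({"A": data})
        res = tukey_posthoc(tab, "A", STAGES).set_index("comparison")
        n, s = data.shape
        grand = data.mean()
        resid = data - data.mean(1, keepdims=True) - data.mean(0) + grand
        ms_err = (resid**2).sum() / ((s - 1) * (n - 1))
        diff = data[:, 1].mean() - data[:, 0].mean()
        q = abs(diff) / np.sqrt(ms_err / n)
        p = sps.studentized_range.sf(q, s, (s - 1) * (n - 1))
        assert res.loc["subacute_vs_acute"].p_value == pytest.approx(p, abs=1e-10)


class TestDeltaCorrelation:
    def make_table(self, dv, ds, rng):
        n = len(dv)
        v1 = rng.normal(0.5, 0.05, n)
        data = np.column_stack([v1, v1 + dv, v1])
        s1 = rng.normal(30, 5, n)
        scores = np.column_stack([s1, s1 + 1, s1 + ds])
        return cohort_from_arrays({"A": data}, scores=scores)

    def test_exact_linear_coupling_gives_unit_r(self, rng):
        dv = rng.normal(0, 0.1, 10)
        tab = self.make_table(dv, 2 * dv, rng)
        res = delta_correlation(tab, "A", "acute", "subacute", "acute", "early_chronic")
        assert res.statistic[0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_coupling_gives_minus_one(self, rng):
        dv = rng.normal(0, 0.1, 10)
        tab = self.make_table(dv, -dv, rng)
        res = delta_correlation(tab, "A", "acute", "subacute", "acute", "early_chronic")
        assert res.statistic[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scipy_pearson(self, rng):
        dv = rng.normal(0, 0.1, 12)
        ds = 5 * dv + rng.normal(0, 0.2, 12)
        tab = self.make_table(dv, ds, rng)
        res = delta_correlation(tab, "A", "acute", "subacute", "acute", "early_chronic")
        r, p = sps.pearsonr(dv, ds)
        assert res.statistic[0] == pytest.approx(r, abs=1e-10)
        assert res.p_value[0] == pytest.approx(p, abs=1e-10)

    def test_too_few_cases_rejected(self, rng):
        tab = self.make_table(np.array([0.1, -0.1]), np.array([1.0, -1.0]), rng)
        with pytest.raises(ValueError, match="complete cases"):
            delta_correlation(tab, "A", "acute", "subacute", "acute", "early_chronic")


class TestPower:
    def test_raised_switching_region_is_top_ranked(self):
        """A region whose switching intensity is raised in patients at one
        stage should carry the largest |t| in nearly every replicate."""
        from tempovar.pipeline import build_cohort_table
        from tempovar.synthetic import (
            BehaviorCoupling,
            CohortDesign,
            default_model,
            simulate_cohort,
        )

        model = default_model()
        top = 0
        n_rep = 50
        for seed in range(n_rep):
            design = CohortDesign(
                n_per_group=19,
                n_volumes=200,
                effect_map={("patient", "acute", "STG_R"): 10.0},
                coupling=BehaviorCoupling(slope=0.0, noise_sd=4.0),
                subject_effect_sd=0.0,
                seed=40_000 + seed,
            )
            cohort, _ = simulate_cohort(design, model)
            tab = build_cohort_table(cohort.series, cohort.metadata)
            res = two_sample_t_per_region(tab, "acute").set_index("region")
            if res.statistic.abs().idxmax() == "STG_R":
                top += 1
        assert top >= 45  # >= 90% of replicates


class TestRendering:
    def test_table2_shape(self, rng):
        pat = rng.normal(0.4, 0.01, size=(6, 3))
        con = rng.normal(0.8, 0.01, size=6)
        tab = cohort_from_arrays(
            {"PreCG_L": pat, "PreCG_R": pat + 0.4}, {"PreCG_L": con, "PreCG_R": con}
        )
        t_results = {s: two_sample_t_per_region(tab, s) for s in STAGES}
        out = render_table2(t_results)
        assert list(out.columns)[:3] == ["region", "T_acute", "P_acute"]
        assert set(out.region) == {"PreCG_L"}  # only the significant region

    def test_table2_empty_result_keeps_header(self):
        v = np.array([0.5, 0.6, 0.7])
        tab = cohort_from_arrays({"A": np.tile(v[:, None], (1, 3))}, {"A": v})
        out = render_table2({s: two_sample_t_per_region(tab, s) for s in STAGES})
        assert len(out) == 0

    def test_table3_columns(self, rng):
        data = rng.normal(0, 0.01, size=(10, 3)) + np.array([0.0, 0.5, 0.5])
        tab = cohort_from_arrays({"A": data})
        anova = rm_anova_per_region(tab, STAGES)
        posthoc = {"A": tukey_posthoc(tab, "A", STAGES)}
        out = render_table3(anova, posthoc)
        assert "F" in out.columns and "P_anova" in out.columns
        assert "diff_subacute_vs_acute" in out.columns
        assert "P_early_chronic_vs_subacute" in out.columns
        assert len(out) == 1
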