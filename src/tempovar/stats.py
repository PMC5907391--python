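"""Group, longitudinal and brain-behavior statistics on cohort tables.

Input is a long-format cohort table with one row per
(subject, stage, region): columns ``subject_id``, ``group`` (patient /
control), ``stage``, ``region``, ``V_mean`` (temporal variability averaged
across window lengths) and ``score`` (behavioral scale, absent for
controls).  The stages implemented:

* per-region two-sample t-tests, patients vs controls at one stage
  (pooled-variance Student t by default; uncorrected p, alpha 0.005);
* per-region one-way repeated-measures ANOVA across the patient stages
  (F = MS_stage / MS_(stage x subject); alpha 0.01), never including
  controls;
* Tukey HSD post hoc stage-pair comparisons using the repeated-measures
  error term and the studentized-range distribution (alpha 0.05);
* Pearson correlation between per-patient changes in one region's
  variability and changes in the behavioral score.

No multiple-testing correction is applied anywhere; every p-value is
reported as uncorrected.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "two_sample_t_per_region",
    "rm_anova_per_region",
    "tukey_posthoc",
    "delta_correlation",
    "render_table2",
    "render_table3",
]

RESULT_COLUMNS = [
    "comparison",
    "region",
    "statistic_name",
    "statistic",
    "p_value",
    "significant",
]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "group", "stage", "region", "V_mean"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject_id", "stage", "region"])
    if dup.any():
        raise ValueError("duplicate (subject, stage, region) rows in cohort table")
    return table


def two_sample_t_per_region(
    table: pd.DataFrame,
    stage: str,
    control_stage: str = "baseline",
    alpha: float = 0.005,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Patients (at ``stage``) vs controls (at ``control_stage``), per region.

    Pooled-variance Student t by default (``equal_var=False`` for Welch).
    Sign convention: negative t means patients lower than controls.
    """
    _check_table(table)
    pat = table[(table.group == "patient") & (table.stage == stage)]
    con = table[(table.group == "control") & (table.stage == control_stage)]
    if pat.empty:
        raise ValueError(f"no patient rows at stage {stage!r}")
    if con.empty:
        raise ValueError(f"no control rows at stage {control_stage!r}")
    rows = []
    for region, pg in pat.groupby("region", sort=False):
        cg = con[con.region == region]
        a, b = pg.V_mean.to_numpy(), cg.V_mean.to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 subjects per group for region {region!r}")
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "comparison": f"patients_{stage}_vs_controls",
                "region": region,
                "statistic_name": "t",
                "statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _stage_matrix(
    table: pd.DataFrame, region: str, stages: tuple[str, ...]
) -> np.ndarray:
    """Subjects x stages matrix of V for patients, erroring on missing cells."""
    pat = table[(table.group == "patient") & (table.region == region)]
    piv = pat.pivot(index="subject_id", columns="stage", values="V_mean")
    for stage in stages:
        if stage not in piv.columns:
            raise ValueError(f"no patient data at stage {stage!r} for {region!r}")
    piv = piv[list(stages)]
    if piv.isna().any().any():
        subj = piv.index[piv.isna().any(axis=1)][0]
        stage = piv.columns[piv.isna().any(axis=0)][0]
        raise ValueError(f"missing cell: subject {subj!r}, stage {stage!r}")
    return piv.to_numpy()


def _rm_anova_terms(data: np.ndarray) -> tuple[float, float, int, int]:
    """Return (F, MS_error, df_stage, df_error) for one-way RM-ANOVA."""
    n, s = data.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs >= 3 subjects")
    if s < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 stages")
    grand = data.mean()
    stage_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_stage = n * np.sum((stage_means - grand) ** 2)
    resid = data - subj_means[:, None] - stage_means[None, :] + grand
    ss_error = np.sum(resid**2)
    df_stage = s - 1
    df_error = (s - 1) * (n - 1)
    ms_stage = ss_stage / df_stage
    ms_error = ss_error / df_error
    F = ms_stage / ms_error if ms_error > 0 else np.inf
    return float(F), float(ms_error), df_stage, df_error


def rm_anova_per_region(
    table: pd.DataFrame,
    stages: tuple[str, ...] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-way repeated-measures ANOVA across patient stages, per region.

    F = MS_stage / MS_(stage x subject) on (s-1, (s-1)(n-1)) degrees of
    freedom; no sphericity correction.  Controls never enter.
    """
    _check_table(table)
    stages = stages or _patient_stages(table)
    rows = []
    for region in table[table.group == "patient"].region.unique():
        data = _stage_matrix(table, region, stages)
        F, _, df1, df2 = _rm_anova_terms(data)
        p = float(sps.f.sf(F, df1, df2))
        rows.append(
            {
                "comparison": "stages_" + "_".join(stages),
                "region": region,
                "statistic_name": "F",
                "statistic": F,
                "p_value": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _patient_stages(table: pd.DataFrame) -> tuple[str, ...]:
    order = ["acute", "subacute", "early_chronic"]
    present = list(dict.fromkeys(table[table.group == "patient"].stage))
    present.sort(key=lambda s: order.index(s) if s in order else len(order))
    return tuple(present)


def tukey_posthoc(
    table: pd.DataFrame,
    region: str,
    stages: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD stage-pair comparisons with the repeated-measures error term.

    For every stage pair the mean difference (later stage minus earlier
    stage) is reported with a studentized-range p-value computed from
    q = |diff| / sqrt(MS_error / n) on (n_stages, df_error) where MS_error
    and df_error come from the repeated-measures ANOVA — the only error
    term consistent with the within-subject design.
    """
    _check_table(table)
    stages = stages or _patient_stages(table)
    data = _stage_matrix(table, region, stages)
    n, s = data.shape
    _, ms_error, _, df_error = _rm_anova_terms(data)
    se = np.sqrt(ms_error / n)
    rows = []
    for i, j in itertools.combinations(range(s), 2):
        diff = float(data[:, j].mean() - data[:, i].mean())  # later - earlier
        if se > 0:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, s, df_error))
        else:
            p = 1.0 if diff == 0 else 0.0
        rows.append(
            {
                "comparison": f"{stages[j]}_vs_{stages[i]}",
                "region": region,
                "statistic_name": "mean_diff",
                "statistic": diff,
                "p_value": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def delta_correlation(
    table: pd.DataFrame,
    region: str,
    from_stage: str,
    to_stage: str,
    score_from: str | None = None,
    score_to: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation of per-patient dV against dScore.

    dV = V(to_stage) - V(from_stage) for ``region``; dScore =
    score(score_to) - score(score_from) (defaulting to the same stage
    pair).  Patients missing either stage or either score are dropped;
    fewer than 3 complete cases is an error.
    """
    _check_table(table)
    if "score" not in table.columns:
        raise ValueError("cohort table has no score column")
    score_from = score_from or from_stage
    score_to = score_to or to_stage
    pat = table[(table.group == "patient") & (table.region == region)]
    v = pat.pivot(index="subject_id", columns="stage", values="V_mean")
    sc = (
        table[table.group == "patient"]
        .drop_duplicates(["subject_id", "stage"])
        .pivot(index="subject_id", columns="stage", values="score")
    )
    for stage, frame, what in [
        (from_stage, v, "variability"),
        (to_stage, v, "variability"),
        (score_from, sc, "score"),
        (score_to, sc, "score"),
    ]:
        if stage not in frame.columns:
            raise ValueError(f"no {what} data at stage {stage!r}")
    dv = v[to_stage] - v[from_stage]
    ds = sc[score_to] - sc[score_from]
    joined = pd.concat([dv.rename("dv"), ds.rename("ds")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError(
            f"need >= 3 complete cases, got {len(joined)} for region {region!r}"
        )
    r, p = sps.pearsonr(joined.dv, joined.ds)
    return pd.DataFrame(
        [
            {
                "comparison": (
                    f"dV[{from_stage}->{to_stage}]~"
                    f"dScore[{score_from}->{score_to}]"
                ),
                "region": region,
                "statistic_name": "r",
                "statistic": float(r),
                "p_value": float(p),
                "significant": bool(p < 0.05),
            }
        ],
        columns=RESULT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# report rendering


def render_table2(
    t_results: dict[str, pd.DataFrame], significant_only: bool = True
) -> pd.DataFrame:
    """Wide patients-vs-controls report: one (T, P) column pair per stage.

    Regions are sorted ipsilesional (left, ``*_L``) first, then
    contralesional, then midline, alphabetically within each block.
    """
    frames = []
    for stage, res in t_results.items():
        sub = res[res.significant] if significant_only else res
        frames.append(
            sub.set_index("region")[["statistic", "p_value"]].rename(
                columns={"statistic": f"T_{stage}", "p_value": f"P_{stage}"}
            )
        )
    out = pd.concat(frames, axis=1) if frames else pd.DataFrame()
    return out.loc[_sort_regions(out.index)].reset_index(names="region")


def render_table3(
    anova: pd.DataFrame,
    posthoc: dict[str, pd.DataFrame],
    significant_only: bool = True,
) -> pd.DataFrame:
    """Wide longitudinal report: ANOVA F/P plus per-pair mean-diff/P columns."""
    sub = anova[anova.significant] if significant_only else anova
    out = sub.set_index("region")[["statistic", "p_value"]].rename(
        columns={"statistic": "F", "p_value": "P_anova"}
    )
    for region, ph in posthoc.items():
        for _, row in ph.iterrows():
            out.loc[region, f"diff_{row.comparison}"] = row.statistic
            out.loc[region, f"P_{row.comparison}"] = row.p_value
    return out.loc[_sort_regions(out.index)].reset_index(names="region")


def _sort_regions(regions) -> list:
    def key(name: str):
        name = str(name)
        side = 0 if name.endswith("_L") else (1 if name.endswith("_R") else 2)
        return (side, name)

    return sorted(regions, key=key)
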