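"""Cohort stratification, per-subject assessment, summary tables and statistics.

This module wires the anthropometric primitives and the reference model into
a cohort-level workflow:

* risk stratification — a subject is high CV risk if CACS >= 10 Agatston
  units, or hypertensive, or diabetic (treated type 2), or a smoker with
  dyslipidemia; everyone else is low risk,
* the reference filter — normal-BMI, low-risk subjects, the stratum on
  which the reference regression is fit,
* per-subject THV assessment (expected / standard / limits / abnormality /
  indexation),
* subgroup mean tables and abnormality-prevalence tables over
  sex x BMI class x risk class,
* the simple two-group statistics used to compare strata (Student/Welch t,
  Pearson chi-square) and measurement-agreement statistics (mean
  difference, ICC, limits of agreement, Pearson r).

P-values are reported raw; no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .anthropometry import (
    BmiClass,
    SubjectRecord,
    derive_anthropometry,
)
from .reference_model import (
    ReferenceModel,
    ThvAssessment,
    classify_thv,
    expected_thv,
    index_thv,
    prediction_limits,
    standard_thv,
)

__all__ = [
    "RiskProfile",
    "AgreementStats",
    "risk_classify",
    "reference_filter",
    "assess_cohort",
    "subgroup_table",
    "prevalence_table",
    "two_sample_t",
    "chi_square_2xk",
    "agreement_stats",
]

CACS_THRESHOLD = 10.0  # Agatston units; >= 10 triggers the high-risk class

SUBGROUP_KEYS = ["sex", "bmi_class", "risk_class"]
SUMMARY_VARIABLES = [
    "thv_measured",
    "thv_expected",
    "thv_standard",
    "thv_per_h",
    "thv_per_bsa",
    "index_correction",
    "delta",
]


@dataclass(frozen=True)
class RiskProfile:
    """Cardiovascular risk class of one subject with its trigger reasons."""

    risk_class: str  # "low" | "high"
    is_reference: bool  # low risk AND normal BMI
    reasons: Tuple[str, ...] = ()


@dataclass(frozen=True)
class AgreementStats:
    """Repeated-measurement agreement summary (Bland-Altman style + ICC)."""

    n: int
    mean_difference: float  # mL
    mean_difference_pct: float  # % of the pairwise mean
    sd_difference: float  # mL
    loa_lower: float  # mL, mean difference - 1.96 SD
    loa_upper: float  # mL, mean difference + 1.96 SD
    icc: Optional[float]  # two-way random, absolute agreement, single measure
    icc_defined: bool
    pearson_r: float
    icc_model: str = "ICC2 (two-way random, absolute agreement, single measure)"


def risk_classify(record: SubjectRecord) -> RiskProfile:
    """Assign the §-style low/high CV-risk class with its trigger list.

    High risk iff CACS >= 10 AU, or hypertension, or treated type 2
    diabetes, or simultaneous smoking and dyslipidemia.  ``is_reference``
    additionally requires a normal BMI.
    """
    reasons: List[str] = []
    if record.cacs >= CACS_THRESHOLD:
        reasons.append("CACS>=10")
    if record.sah:
        reasons.append("SAH")
    if record.t2dm:
        reasons.append("T2DM")
    if record.smoker and record.hl:
        reasons.append("smoking+HL")
    risk = "high" if reasons else "low"
    anthro = derive_anthropometry(record.height, record.weight)
    return RiskProfile(
        risk_class=risk,
        is_reference=(risk == "low" and anthro.bmi_class is BmiClass.NORMAL),
        reasons=tuple(reasons),
    )


def reference_filter(records: Sequence[SubjectRecord]) -> List[SubjectRecord]:
    """Keep the reference stratum: normal BMI and low CV risk, order preserved."""
    return [r for r in records if risk_classify(r).is_reference]


def assess_cohort(
    records: Sequence[SubjectRecord], model: ReferenceModel
) -> List[ThvAssessment]:
    """Assess every subject against the reference model.

    For each record: expected THV at the subject's height and h-BSA index,
    the standard-human THV, the symmetric prediction limits, the
    measured-minus-upper-limit difference and abnormality flag (undetermined
    when no THV was measured), and the height/BSA indexed values with their
    correction.  Deterministic given inputs.
    """
    out: List[ThvAssessment] = []
    for rec in records:
        anthro = derive_anthropometry(rec.height, rec.weight)
        exp = expected_thv(model, rec.height, anthro.d)
        std = standard_thv(model, rec.height)
        lower, upper = prediction_limits(model, exp)
        if rec.thv_measured is None:
            delta = None
            abnormal = None
            per_h = per_bsa = corr = None
        else:
            delta = rec.thv_measured - upper
            abnormal = classify_thv(rec.thv_measured, upper) == "abnormal"
            per_h, per_bsa, corr = index_thv(rec.thv_measured, rec.height, anthro.bsa)
        out.append(
            ThvAssessment(
                id=rec.id,
                thv_expected=exp,
                thv_standard=std,
                thv_lower=lower,
                thv_upper=upper,
                delta=delta,
                abnormal=abnormal,
                thv_per_h=per_h,
                thv_per_bsa=per_bsa,
                index_correction=corr,
            )
        )
    return out


def _strata_frame(
    assessments: Sequence[ThvAssessment], records: Sequence[SubjectRecord]
) -> pd.DataFrame:
    if len(assessments) != len(records):
        raise ValueError("assessments and records must be aligned")
    rows = []
    for rec, a in zip(records, assessments):
        if rec.id != a.id:
            raise ValueError(f"record/assessment id mismatch: {rec.id} vs {a.id}")
        anthro = derive_anthropometry(rec.height, rec.weight)
        profile = risk_classify(rec)
        rows.append(
            {
                "id": rec.id,
                "sex": rec.sex.value,
                "bmi_class": anthro.bmi_class.value,
                "risk_class": profile.risk_class,
                "thv_measured": rec.thv_measured,
                "thv_expected": a.thv_expected,
                "thv_standard": a.thv_standard,
                "thv_per_h": a.thv_per_h,
                "thv_per_bsa": a.thv_per_bsa,
                "index_correction": a.index_correction,
                "delta": a.delta,
                "abnormal": a.abnormal,
            }
        )
    return pd.DataFrame(rows)


def subgroup_table(
    assessments: Sequence[ThvAssessment],
    records: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Per-(sex, BMI class, risk class) means and SDs of the THV quantities.

    One row per non-empty cell; SD is NaN (flagged by ``sd_defined``) for
    single-record cells.  Values are kept at full precision; round only when
    rendering.
    """
    df = _strata_frame(assessments, records)
    if df.empty:
        cols = SUBGROUP_KEYS + ["n", "sd_defined"]
        for v in SUMMARY_VARIABLES:
            cols += [f"{v}_mean", f"{v}_sd"]
        return pd.DataFrame(columns=cols)
    rows = []
    for keys, g in df.groupby(SUBGROUP_KEYS, sort=True, observed=True):
        row = dict(zip(SUBGROUP_KEYS, keys))
        row["n"] = len(g)
        row["sd_defined"] = len(g) >= 2
        for v in SUMMARY_VARIABLES:
            vals = g[v].dropna().astype(float)
            row[f"{v}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{v}_sd"] = vals.std(ddof=1) if len(vals) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def prevalence_table(
    assessments: Sequence[ThvAssessment],
    records: Sequence[SubjectRecord],
    strata: Sequence[str] = ("sex", "bmi_class", "risk_class"),
) -> pd.DataFrame:
    """Counts and percentage of abnormal THV per stratum, plus a totals row.

    Subjects without a measured THV (undetermined abnormality) are excluded
    from the within/abnormal counts and reported in ``n_undetermined``.
    The totals row equals the column sums of the strata rows.
    """
    strata = list(strata)
    unknown = set(strata) - set(SUBGROUP_KEYS)
    if unknown:
        raise ValueError(f"unknown strata: {sorted(unknown)}")
    df = _strata_frame(assessments, records)
    cols = strata + ["n_within", "n_abnormal", "n_undetermined", "percent_abnormal"]
    if df.empty:
        return pd.DataFrame(columns=cols)

    def _summary(g: pd.DataFrame) -> dict:
        determined = g["abnormal"].notna()
        n_ab = int((g["abnormal"] == True).sum())  # noqa: E712 — column holds object NaNs
        n_within = int(determined.sum()) - n_ab
        n_det = n_within + n_ab
        return {
            "n_within": n_within,
            "n_abnormal": n_ab,
            "n_undetermined": int((~determined).sum()),
            "percent_abnormal": 100.0 * n_ab / n_det if n_det else np.nan,
        }

    rows = []
    for keys, g in df.groupby(strata, sort=True, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append({**dict(zip(strata, keys)), **_summary(g)})
    total = {**{k: "total" for k in strata}, **_summary(df)}
    rows.append(total)
    return pd.DataFrame(rows, columns=cols)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test; pooled variance by default (classic
    Student), Welch with ``equal_var=False``.  Returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_2xk(table) -> Tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns (chi2, df, p) with df = (rows - 1)(cols - 1).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("counts must be non-negative and finite")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def agreement_stats(pairs) -> AgreementStats:
    """Agreement between paired measurements of the same quantity.

    Computes the mean difference (mL and % of the pairwise mean), the
    Bland-Altman 95% limits of agreement (mean +/- 1.96 SD of differences),
    Pearson r, and the intraclass correlation coefficient (two-way random
    effects, absolute agreement, single measure).  The ICC is flagged
    undefined when the pairs carry no between-subject variance.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    a, b = arr[:, 0], arr[:, 1]
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    pair_mean = float(((a + b) / 2).mean())
    mean_diff_pct = 100.0 * mean_diff / pair_mean if pair_mean != 0 else np.nan

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        icc, icc_defined = None, False
        pearson = np.nan
    else:
        import pingouin as pg

        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile(["first", "second"], n),
                "value": arr.ravel(),
            }
        )
        icc_tab = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="value"
        )
        # absolute-agreement single-measure ICC; the label differs by version
        match = icc_tab["Type"].isin(["ICC2", "ICC(A,1)"])
        icc_val = float(icc_tab.loc[match, "ICC"].iloc[0])
        icc_defined = np.isfinite(icc_val)
        icc = icc_val if icc_defined else None
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            pearson = np.nan
        else:
            pearson = float(stats.pearsonr(a, b).statistic)

    return AgreementStats(
        n=n,
        mean_difference=mean_diff,
        mean_difference_pct=float(mean_diff_pct),
        sd_difference=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        icc=icc,
        icc_defined=icc_defined,
        pearson_r=pearson,
    )
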