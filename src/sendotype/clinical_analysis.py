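"""Demographic statistics, renal function estimation, and trajectory regressions.

Covers the clinical side of sendotype discovery: chi-squared contrasts of
categorical demographics across CKD severity groups, one-way ANOVA (including
directly from published n/mean/SD summaries), the MDRD eGFR estimating
equation with KDIGO staging, per-protein OLS regressions of NPX against
log2 follow-up renal metrics, and cohort-level clinical comparisons between
the discovered endotype clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ClinicalTable

logger = logging.getLogger("sendotype")

__all__ = [
    "SummaryGroup",
    "RegressionFit",
    "anova_from_summary",
    "chi_squared_test",
    "mdrd_egfr",
    "kdigo_stage",
    "severity_group",
    "trajectory_regression",
    "cohort_clinical_compare",
]


@dataclass(frozen=True)
class SummaryGroup:
    """Published per-group summary: sample size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each summary group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def anova_from_summary(groups: Sequence[SummaryGroup]) -> tuple[float, int, int, float]:
    """One-way ANOVA computed from per-group (n, mean, sd) summaries.

    Algebraically identical to raw-data one-way ANOVA when the summaries are
    exact: SSB = sum n_i (m_i - m)^2, SSW = sum (n_i - 1) s_i^2.

    Returns (F, df_between, df_within, p).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    total_n = ns.sum()
    grand_mean = float((ns * means).sum() / total_n)
    ssb = float((ns * (means - grand_mean) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1 = len(groups) - 1
    df2 = int(total_n) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f_stat = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, df2, p


def anova_from_raw(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """Raw-data one-way ANOVA through the same formulas (cross-check entry point)."""
    summaries = [
        SummaryGroup(n=len(g), mean=float(np.mean(g)), sd=float(np.std(g, ddof=1)))
        for g in groups
    ]
    return anova_from_summary(summaries)


def chi_squared_test(table: np.ndarray | Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction (the demographic tables here have df = 2).
    Returns (chi2, df, p).
    """
    table = np.asarray(table, dtype=float)
    if table.size == 0 or table.sum() == 0:
        raise ValueError("empty contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


#: IDMS-traceable re-expressed MDRD constant; the original study-era constant is 186.
MDRD_CONSTANT = 175.0
UMOL_PER_MGDL = 88.4


def mdrd_egfr(
    creatinine_umol_l: float | np.ndarray,
    age_years: float | np.ndarray,
    sex: str | np.ndarray,
    black: bool | np.ndarray = False,
    constant: float = MDRD_CONSTANT,
) -> float | np.ndarray:
    """MDRD estimated GFR (mL/min/1.73 m^2) from serum creatinine, age, sex, race.

    eGFR = constant * (Scr/88.4)^-1.154 * age^-0.203 * 0.742[female] * 1.212[black]
    with creatinine in umol/L (divided by 88.4 to convert to mg/dL).
    """
    creat = np.asarray(creatinine_umol_l, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if (creat <= 0).any() or (age <= 0).any():
        raise ValueError("creatinine and age must be positive")
    sex_arr = np.asarray(sex)
    female = sex_arr == "female" if sex_arr.dtype.kind in "UO" else sex_arr.astype(bool)
    egfr = constant * (creat / UMOL_PER_MGDL) ** -1.154 * age**-0.203
    egfr = egfr * np.where(female, 0.742, 1.0) * np.where(np.asarray(black), 1.212, 1.0)
    return float(egfr) if egfr.ndim == 0 else egfr


def creatinine_from_egfr(
    egfr: float | np.ndarray,
    age_years: float | np.ndarray,
    sex: str | np.ndarray,
    black: bool | np.ndarray = False,
    constant: float = MDRD_CONSTANT,
) -> float | np.ndarray:
    """Invert the MDRD equation: serum creatinine (umol/L) giving the stated eGFR."""
    egfr = np.asarray(egfr, dtype=float)
    if (egfr <= 0).any():
        raise ValueError("eGFR must be positive")
    sex_arr = np.asarray(sex)
    female = sex_arr == "female" if sex_arr.dtype.kind in "UO" else sex_arr.astype(bool)
    age = np.asarray(age_years, dtype=float)
    base = constant * age**-0.203 * np.where(female, 0.742, 1.0) * np.where(np.asarray(black), 1.212, 1.0)
    creat = UMOL_PER_MGDL * (egfr / base) ** (-1.0 / 1.154)
    return float(creat) if creat.ndim == 0 else creat


_KDIGO_BINS = (
    (90.0, "G1"),
    (60.0, "G2"),
    (45.0, "G3a"),
    (30.0, "G3b"),
    (15.0, "G4"),
    (-np.inf, "G5"),
)

_SEVERITY_BY_STAGE = {
    "G1": "mild",
    "G2": "mild",
    "G3a": "mild",
    "G3b": "moderate",
    "G4": "severe",
    "G5": "severe",
}


def kdigo_stage(egfr: float) -> str:
    """KDIGO CKD stage from eGFR: G1 >=90, G2 60-89, G3a 45-59, G3b 30-44, G4 15-29, G5 <15."""
    if not np.isfinite(egfr) or egfr < 0:
        raise ValueError(f"invalid eGFR {egfr!r}")
    for lower, stage in _KDIGO_BINS:
        if egfr >= lower:
            return stage
    return "G5"


def severity_group(stage: str) -> str:
    """Severity grouping: mild = stages <=3a, moderate = 3b, severe = 4 and 5.

    Stage G1 (preserved eGFR with kidney damage) is grouped with mild.
    """
    try:
        return _SEVERITY_BY_STAGE[stage]
    except KeyError:
        raise ValueError(f"unknown KDIGO stage {stage!r}") from None


def trajectory_regression(
    npx: np.ndarray | Sequence[float],
    outcome: np.ndarray | Sequence[float],
) -> RegressionFit:
    """OLS of NPX (response) on log2(follow-up outcome) (regressor).

    Matches the trajectory-plot convention: protein expression on the y axis,
    log2 eGFR or log2 creatinine on the x axis.  The outcome must be positive;
    log2 is applied here.
    """
    npx = np.asarray(npx, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if npx.shape != outcome.shape or npx.ndim != 1:
        raise ValueError("npx and outcome must be 1-D arrays of equal length")
    if len(npx) < 3:
        raise ValueError("trajectory regression needs n >= 3")
    if (outcome <= 0).any():
        raise ValueError("outcome values must be positive (log2 is applied internally)")
    x = np.log2(outcome)
    if np.ptp(x) == 0:
        raise ValueError("outcome has zero variance on the log2 scale")
    res = stats.linregress(x, npx)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(npx),
    )


_COMPARE_VARIABLES = (
    "age",
    "urea",
    "egfr_baseline",
    "egfr_followup",
    "creatinine_baseline",
    "creatinine_followup",
)


def cohort_clinical_compare(
    clinical: ClinicalTable,
    cluster_labels: pd.Series,
    variables: Iterable[str] = _COMPARE_VARIABLES,
) -> pd.DataFrame:
    """Welch contrasts of clinical variables between severe- and mild-cluster cohorts.

    ``cluster_labels`` maps patient id -> cohort name ("severe-cluster" /
    "mild-cluster").  Returns one row per variable with group means, the Welch
    two-tailed p, and the direction flag ("higher_in_severe" /
    "lower_in_severe" / "equal").
    """
    from .differential_expression import welch_t_test

    labels = cluster_labels.astype(str)
    data = clinical.data.loc[labels.index]
    rows = []
    for var in variables:
        vals = pd.to_numeric(data[var], errors="coerce")
        severe = vals[labels == "severe-cluster"].dropna().to_numpy()
        mild = vals[labels == "mild-cluster"].dropna().to_numpy()
        t, df, p = welch_t_test(severe, mild)
        diff = severe.mean() - mild.mean()
        direction = "higher_in_severe" if diff > 0 else ("lower_in_severe" if diff < 0 else "equal")
        rows.append({
            "variable": var,
            "mean_severe": float(severe.mean()),
            "mean_mild": float(mild.mean()),
            "welch_t": t,
            "welch_df": df,
            "p_value": p,
            "direction": direction,
        })
    return pd.DataFrame(rows).set_index("variable")


def clinical_long_format(
    clinical: ClinicalTable,
    cluster_labels: pd.Series,
    variables: Iterable[str] = _COMPARE_VARIABLES,
) -> pd.DataFrame:
    """Violin-plot-ready long table: one row per (patient, variable)."""
    labels = cluster_labels.astype(str)
    data = clinical.data.loc[labels.index]
    frames = []
    for var in variables:
        frames.append(pd.DataFrame({
            "patient_id": data.index,
            "cohort": labels.values,
            "variable": var,
            "value": pd.to_numeric(data[var], errors="coerce").values,
        }))
    return pd.concat(frames, ignore_index=True)
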