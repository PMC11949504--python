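"""Welch differential expression between sendotype cohorts.

NPX is already on a log2 scale, so the difference of group means is directly
the log2 fold change.  Per-protein Welch two-tailed t-tests (unequal
variances between a severe and a milder disease cohort) are adjusted with
Benjamini-Hochberg FDR, and tables ready for volcano and heatmap rendering
are exported as plain CSV-able DataFrames.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import NPXMatrix, SenescenceLabels

logger = logging.getLogger("sendotype")

__all__ = [
    "welch_t_test",
    "log2_fold_change",
    "bh_adjust",
    "de_table",
    "volcano_table",
    "heatmap_table",
]


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-tailed t-test; returns (t, Welch-Satterthwaite df, p).

    t = (mean(x) - mean(y)) / sqrt(s1^2/n1 + s2^2/n2).  Degenerate cases:
    both variances zero with equal means gives (0, df, 1); with different
    means gives p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t_test needs n >= 2 in each group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        df = float(n1 + n2 - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        logger.warning("welch_t_test: zero variance in both groups with different means")
        t = float("inf") if x.mean() > y.mean() else float("-inf")
        return t, df, 0.0
    se2 = v1 / n1 + v2 / n2
    t = float((x.mean() - y.mean()) / np.sqrt(se2))
    with np.errstate(invalid="ignore"):
        df = float(se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)))
    if not np.isfinite(df):  # subnormal variances underflow in the ratio
        df = float(n1 + n2 - 2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def log2_fold_change(x: Sequence[float], y: Sequence[float]) -> float:
    """Group-mean difference on the NPX (log2) scale: mean(x) - mean(y)."""
    return float(np.mean(x) - np.mean(y))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    m: NPXMatrix,
    cohorts: pd.Series,
    labels: SenescenceLabels | None = None,
) -> pd.DataFrame:
    """Per-protein Welch DE between the severe- and mild-cluster cohorts.

    ``cohorts`` maps patient id -> "severe-cluster" / "mild-cluster".
    log2_fc is severe mean minus mild mean.  Returns one row per protein
    sorted by p-value, with BH-adjusted p and the senescence flag.
    """
    values = m.complete_values()
    cohorts = cohorts.astype(str)
    order = [m.patient_ids.index(p) for p in cohorts.index]
    values = values[order]
    severe_mask = (cohorts == "severe-cluster").to_numpy()
    mild_mask = (cohorts == "mild-cluster").to_numpy()
    if severe_mask.sum() < 2 or mild_mask.sum() < 2:
        raise ValueError("each cohort needs at least two patients for Welch DE")
    rows = []
    for j, protein in enumerate(m.protein_ids):
        x = values[severe_mask, j]
        y = values[mild_mask, j]
        t, df, p = welch_t_test(x, y)
        rows.append({
            "protein": protein,
            "log2_fc": log2_fold_change(x, y),
            "t_stat": t,
            "df": df,
            "p_value": p,
        })
    table = pd.DataFrame(rows).set_index("protein")
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    table["senescent"] = [
        (protein in labels) if labels is not None else False for protein in table.index
    ]
    return table.sort_values(["p_value", "protein"], kind="mergesort")


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot export: log2 fold change vs -log10 p per protein."""
    out = de[["log2_fc", "p_value", "adj_p", "senescent"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out


def heatmap_table(
    de: pd.DataFrame,
    m: NPXMatrix,
    cohorts: pd.Series,
    top_n: int = 25,
) -> pd.DataFrame:
    """Heatmap export: top-N proteins by p, z-scored per protein.

    Rows are proteins, columns patients ordered mild cohort first then severe,
    mirroring the cohort-blocked heatmap layout.
    """
    top = list(de.index[: min(top_n, len(de))])
    sub = m.to_frame()[top]
    cohorts = cohorts.astype(str)
    ordered_patients = list(cohorts[cohorts == "mild-cluster"].index) + list(
        cohorts[cohorts == "severe-cluster"].index
    )
    sub = sub.loc[ordered_patients]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1).replace(0.0, 1.0)
    return z.T
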