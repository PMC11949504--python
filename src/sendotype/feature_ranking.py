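"""Bootstrap-PCA loading-score ranking of proteins.

Proteins are ranked by the magnitude of their loadings on the principal
component that spans the most severity-class variance.  Patients are
resampled with replacement (500 bootstraps by default); within each bootstrap
a PCA is fitted, the class-variance-maximising PC is selected, the loading
vector is sign-aligned to the full-data reference, and the per-protein
median absolute loading across bootstraps is the ranking metric.  Each
ranked protein carries a flag for membership in the senescence label set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_model import NPXMatrix, SenescenceLabels

logger = logging.getLogger("sendotype")

__all__ = [
    "RankedFeatures",
    "zscore_columns",
    "pca_loadings",
    "select_pc",
    "bootstrap_rank",
    "top_k_senescent_fraction",
]


@dataclass
class RankedFeatures:
    """Proteins ordered by median absolute bootstrap loading (non-increasing)."""

    table: pd.DataFrame  # index: protein_id; columns: median_abs_loading, senescent
    selected_pc: int  # 1-based index of the PC chosen on the full data
    n_bootstraps: int

    def __post_init__(self) -> None:
        scores = self.table["median_abs_loading"].to_numpy()
        if np.any(np.diff(scores) > 1e-12):
            raise ValueError("ranking must be non-increasing in median_abs_loading")

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)


def zscore_columns(values: np.ndarray) -> np.ndarray:
    """Per-column z-score; zero-variance columns map to all-zero columns."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = values - mean
    nonzero = sd > 0
    out[:, nonzero] /= sd[nonzero]
    out[:, ~nonzero] = 0.0
    return out


def pca_loadings(
    values: np.ndarray,
    n_components: int,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA on a complete patients x proteins matrix.

    Returns (loadings, explained_variance_ratio, scores): loadings is
    proteins x n_components with unit-norm columns; scores is the centred
    (and, if ``scale``, per-protein standardised) data projected on them.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute first")
    n, p = values.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds min(patients, proteins)")
    x = zscore_columns(values) if scale else values - values.mean(axis=0)
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("matrix has zero variance everywhere")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T
    return loadings, model.explained_variance_ratio_, scores


def select_pc(
    scores: np.ndarray,
    severity_labels: np.ndarray | pd.Series | None,
    n_candidates: int = 10,
) -> int:
    """1-based index of the PC whose scores span the most class variance.

    Operationalised as the maximal one-way ANOVA F of the PC scores across
    severity groups, over the first ``n_candidates`` PCs; ties break toward
    the lower index.  With no labels, PC1 is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n_candidates = min(n_candidates, scores.shape[1])
    if severity_labels is None:
        logger.warning("select_pc: no class labels supplied; defaulting to PC1")
        return 1
    labels = np.asarray(severity_labels)
    classes = [c for c in np.unique(labels) if (labels == c).sum() >= 2]
    if len(classes) < 2:
        raise ValueError("select_pc needs at least two classes with >=2 members")
    best_pc, best_f = 1, -np.inf
    for idx in range(n_candidates):
        groups = [scores[labels == c, idx] for c in classes]
        f_stat, _ = stats.f_oneway(*groups)
        if np.isnan(f_stat):
            f_stat = 0.0
        if f_stat > best_f + 1e-12:
            best_f, best_pc = float(f_stat), idx + 1
    return best_pc


def bootstrap_rank(
    m: NPXMatrix,
    severity_labels: pd.Series | np.ndarray | None,
    senescence: SenescenceLabels | None = None,
    n_bootstraps: int = 500,
    n_candidates: int = 10,
    scale: bool = True,
    seed: int | None = None,
    resample: bool = True,
) -> RankedFeatures:
    """Rank proteins by median absolute bootstrap PCA loading.

    Each bootstrap resamples patients with replacement at full cohort size,
    fits PCA, selects the class-variance PC, sign-aligns that loading vector
    to the full-data reference loading (flip if negatively correlated), and
    records absolute loadings.  ``resample=False`` is a test hook that makes
    every "bootstrap" the full sample, so the ranking reduces to plain
    |loadings|.

    Ties in the median loading break lexicographically by protein id.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    values = m.complete_values()
    labels = None if severity_labels is None else np.asarray(
        severity_labels.loc[m.patient_ids] if isinstance(severity_labels, pd.Series)
        else severity_labels
    )
    n_comp = min(n_candidates, min(values.shape) - 1) or 1
    ref_loadings, _, ref_scores = pca_loadings(values, n_comp, scale=scale)
    ref_pc = select_pc(ref_scores, labels, n_candidates=n_comp)
    ref_vector = ref_loadings[:, ref_pc - 1]

    rng = np.random.default_rng(seed)
    n = values.shape[0]
    abs_loadings = np.empty((n_bootstraps, values.shape[1]))
    for b in range(n_bootstraps):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n) if resample else np.arange(n)
            sample = values[idx]
            if np.any(sample.std(axis=0) > 0):
                break
            logger.warning("bootstrap_rank: zero-variance resample, retrying")
        else:
            raise RuntimeError("bootstrap resampling produced zero-variance samples 10 times")
        boot_labels = None if labels is None else labels[idx]
        loadings, _, boot_scores = pca_loadings(sample, n_comp, scale=scale)
        try:
            pc = select_pc(boot_scores, boot_labels, n_candidates=n_comp)
        except ValueError:  # resample drew a single class
            pc = ref_pc
        vec = loadings[:, pc - 1]
        if float(vec @ ref_vector) < 0:
            vec = -vec
        abs_loadings[b] = np.abs(vec)

    median_abs = np.median(abs_loadings, axis=0)
    table = pd.DataFrame({
        "median_abs_loading": median_abs,
        "senescent": [
            (p in senescence) if senescence is not None else False for p in m.protein_ids
        ],
    }, index=pd.Index(m.protein_ids, name="protein"))
    # descending loading, ties broken by ascending protein id
    table = table.iloc[np.lexsort((table.index.to_numpy(), -table["median_abs_loading"].to_numpy()))]
    return RankedFeatures(table=table, selected_pc=ref_pc, n_bootstraps=n_bootstraps)


def top_k_senescent_fraction(ranked: RankedFeatures, k: int) -> float:
    """Fraction of the top-k ranked proteins flagged as senescence-associated."""
    if k > len(ranked.table):
        raise ValueError("k exceeds the number of ranked proteins")
    top = ranked.table.iloc[:k]
    if not top["senescent"].any() and not ranked.table["senescent"].any():
        logger.warning("top_k_senescent_fraction: no senescence labels supplied")
    return float(top["senescent"].mean()) if k else 0.0
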