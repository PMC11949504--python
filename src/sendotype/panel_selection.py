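"""Silhouette-constrained forward panel selection and cluster validation.

Starting from the top-ranked protein, proteins are added in rank order; at
each step k-means is run for every k in 2..10 and the panel retained is the
longest prefix whose best-over-k mean silhouette stays at or above 0.5.  The
final panel's clusters are validated with the Calinski-Harabasz index, mean
silhouette and within-cluster sum of squares (elbow), and the two clusters
are named mild-/severe-cluster by mean panel NPX.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .feature_ranking import RankedFeatures, zscore_columns
from .io_model import NPXMatrix

logger = logging.getLogger("sendotype")

__all__ = [
    "ClusterAssignment",
    "PanelResult",
    "kmeans",
    "silhouette",
    "calinski_harabasz",
    "forward_panel_selection",
    "name_cohorts",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-patient cluster index
    centroids: np.ndarray  # k x p
    inertia: float  # total within-cluster sum of squares
    patient_ids: list[str] = field(default_factory=list)
    cohort_names: dict[int, str] | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)

    def cohort_series(self) -> pd.Series:
        """Patient id -> cohort name (requires name_cohorts to have run)."""
        if self.cohort_names is None:
            raise ValueError("cohorts not named yet; call name_cohorts")
        return pd.Series(
            [self.cohort_names[int(c)] for c in self.labels],
            index=pd.Index(self.patient_ids, name="patient_id"),
            name="cohort",
        )


@dataclass
class PanelResult:
    panel: list[str]
    step_trace: pd.DataFrame  # columns: step, n_proteins, k, silhouette
    chosen_k: int
    criteria: pd.DataFrame  # index k; columns calinski_harabasz, mean_silhouette, wss

    @property
    def size(self) -> int:
        return len(self.panel)


def kmeans(
    values: np.ndarray,
    k: int,
    n_restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    patient_ids: list[str] | None = None,
    allow_single: bool = False,
) -> ClusterAssignment:
    """Lloyd k-means with k-means++ initialisation, best of ``n_restarts`` by inertia.

    ``allow_single`` permits k = 1 for testing (centroid = column means).
    """
    values = np.asarray(values, dtype=float)
    if k < 2 and not allow_single:
        raise ValueError("k must be >= 2")
    if k > values.shape[0]:
        raise ValueError("k exceeds the number of patients")
    if np.isnan(values).any():
        raise ValueError("k-means requires a complete matrix")
    model = KMeans(
        n_clusters=k, n_init=n_restarts, max_iter=max_iter, tol=tol,
        random_state=None if seed is None else int(seed) % (2**32),
    )
    labels = model.fit_predict(values)
    return ClusterAssignment(
        labels=labels,
        centroids=model.cluster_centers_,
        inertia=float(model.inertia_),
        patient_ids=list(patient_ids) if patient_ids is not None else
        [str(i) for i in range(values.shape[0])],
    )


def silhouette(values: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean); singleton clusters score 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(silhouette_score(np.asarray(values, dtype=float), labels, metric="euclidean"))


def calinski_harabasz(values: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: (SSB/(k-1)) / (SSW/(n-k))."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    n = len(labels)
    if k < 2:
        raise ValueError("calinski_harabasz requires at least two clusters")
    if n == k:
        raise ValueError("calinski_harabasz undefined when every point is its own cluster")
    return float(calinski_harabasz_score(np.asarray(values, dtype=float), labels))


def wss(values: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from cluster centroids."""
    values = np.asarray(values, dtype=float)
    total = 0.0
    for c in np.unique(labels):
        pts = values[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def forward_panel_selection(
    ranked: RankedFeatures,
    m: NPXMatrix,
    k_range: range = range(2, 11),
    threshold: float = 0.5,
    n_restarts: int = 25,
    seed: int | None = None,
    stop_after: int = 10,
    max_panel: int | None = None,
) -> PanelResult:
    """Grow the panel in rank order until the silhouette criterion fails.

    At each step the panel matrix (z-scored per protein) is clustered for
    every k in ``k_range``; a prefix passes when its best-over-k mean
    silhouette is >= ``threshold``.  The returned panel is the longest
    passing prefix.  The scan stops after ``stop_after`` consecutive failing
    prefixes (the silhouette trace declines once uninformative proteins are
    appended) or at ``max_panel`` proteins.

    chosen_k is the k maximising mean silhouette on the final panel;
    Calinski-Harabasz and WSS per k are reported for the validation plots.
    """
    if not len(ranked.table):
        raise ValueError("ranked feature list is empty")
    values = m.complete_values()
    order = [m.protein_ids.index(p) for p in ranked.proteins]
    rng = np.random.default_rng(seed)
    limit = min(len(order), max_panel or len(order), m.n_patients - 1)

    trace_rows = []
    best_prefix = 0
    consecutive_failures = 0
    for step in range(1, limit + 1):
        sub = zscore_columns(values[:, order[:step]])
        best_sil = -np.inf
        for k in k_range:
            if k > sub.shape[0] - 1:
                continue
            assign = kmeans(sub, k, n_restarts=n_restarts,
                            seed=int(rng.integers(2**31)))
            sil = silhouette(sub, assign.labels)
            trace_rows.append({"step": step, "n_proteins": step, "k": k, "silhouette": sil})
            best_sil = max(best_sil, sil)
        if best_sil >= threshold:
            best_prefix = step
            consecutive_failures = 0
        else:
            consecutive_failures += 1
            if consecutive_failures >= stop_after:
                logger.info(
                    "forward_panel_selection: stopping scan at step %d after %d "
                    "consecutive sub-threshold prefixes", step, stop_after,
                )
                break
    trace = pd.DataFrame(trace_rows)
    if best_prefix == 0:
        raise ValueError(
            "no panel prefix reached the silhouette threshold "
            f"{threshold} (max achieved: {trace['silhouette'].max():.3f})"
        )
    panel = ranked.proteins[:best_prefix]

    panel_values = zscore_columns(values[:, order[:best_prefix]])
    crit_rows = {}
    for k in k_range:
        if k > panel_values.shape[0] - 1:
            continue
        assign = kmeans(panel_values, k, n_restarts=n_restarts,
                        seed=int(rng.integers(2**31)))
        crit_rows[k] = {
            "calinski_harabasz": calinski_harabasz(panel_values, assign.labels),
            "mean_silhouette": silhouette(panel_values, assign.labels),
            "wss": wss(panel_values, assign.labels),
        }
    criteria = pd.DataFrame.from_dict(crit_rows, orient="index").rename_axis("k")
    chosen_k = int(criteria["mean_silhouette"].idxmax())
    logger.info("forward_panel_selection: panel of %d proteins, chosen_k=%d",
                len(panel), chosen_k)
    return PanelResult(panel=panel, step_trace=trace, chosen_k=chosen_k, criteria=criteria)


def name_cohorts(
    assignment: ClusterAssignment,
    m: NPXMatrix,
    panel: list[str],
) -> ClusterAssignment:
    """Name clusters by mean panel NPX: highest mean -> severe-cluster.

    Panel proteins are upregulated with disease severity, so the cluster with
    the higher raw-NPX mean over the panel is the severe cohort.  With two
    clusters the other is the mild-cluster; intermediate clusters (k > 2)
    keep index-based names.  Exact ties break toward cluster 0 = mild.
    """
    frame = m.to_frame()[panel].loc[assignment.patient_ids]
    means = {}
    for c in np.unique(assignment.labels):
        means[int(c)] = float(frame.values[assignment.labels == c].mean())
    ordered = sorted(means, key=lambda c: (means[c], c))
    if len(ordered) >= 2 and means[ordered[0]] == means[ordered[-1]]:
        logger.warning("name_cohorts: cluster panel means tie; cluster 0 named mild-cluster")
        ordered = sorted(means)
    names = {c: f"cluster-{c}" for c in means}
    names[ordered[0]] = "mild-cluster"
    names[ordered[-1]] = "severe-cluster"
    assignment.cohort_names = names
    return assignment
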