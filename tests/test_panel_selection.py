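import numpy as np
import pandas as pd
import pytest

from sendotype.feature_ranking import RankedFeatures, bootstrap_rank
from sendotype.io_model import NPXMatrix
from sendotype.panel_selection import (
    calinski_harabasz,
    forward_panel_selection,
    kmeans,
    name_cohorts,
    silhouette,
    wss,
)

from oracles import calinski_harabasz_bruteforce, silhouette_bruteforce

FOUR_POINTS = np.array([[0.0], [0.1], [10.0], [10.1]])
FOUR_LABELS = np.array([0, 0, 1, 1])


def _two_clumps(rng, n=40, d=3, sep=8.0):
    half = n // 2
    values = rng.normal(size=(n, d))
    values[half:] += sep / np.sqrt(d)
    labels = np.repeat([0, 1], [half, n - half])
    return values, labels


class TestKmeans:
    def test_k1_closed_form(self, rng):
        values = rng.normal(size=(12, 3))
        assign = kmeans(values, 1, allow_single=True, seed=0)
        np.testing.assert_allclose(assign.centroids[0], values.mean(axis=0), atol=1e-9)
        assert assign.inertia == pytest.approx(((values - values.mean(axis=0)) ** 2).sum())

    def test_recovers_planted_partition(self, rng):
        values, labels = _two_clumps(rng)
        assign = kmeans(values, 2, seed=1)
        same = (assign.labels == assign.labels[0])
        planted = labels == labels[0]
        assert np.array_equal(same, planted)

    def test_duplicated_rows_leave_centroids_unchanged(self, rng):
        values, _ = _two_clumps(rng, n=20)
        a1 = kmeans(values, 2, seed=2)
        a2 = kmeans(np.vstack([values, values]), 2, seed=2)
        c1 = a1.centroids[np.argsort(a1.centroids[:, 0])]
        c2 = a2.centroids[np.argsort(a2.centroids[:, 0])]
        np.testing.assert_allclose(c1, c2, atol=1e-6)

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError, match="k must be"):
            kmeans(rng.normal(size=(10, 2)), 1)


class TestSilhouette:
    def test_hand_computed_two_pairs(self):
        # a = 0.1, b = 10.05 for every point -> (b-a)/b = 0.99005
        assert silhouette(FOUR_POINTS, FOUR_LABELS) == pytest.approx(0.990, abs=5e-4)

    def test_interleaved_identical_clusters_not_positive(self, rng):
        cloud = rng.normal(size=(15, 2))
        values = np.vstack([cloud, cloud])  # two exactly overlapping clusters
        labels = np.repeat([0, 1], 15)
        assert silhouette(values, labels) <= 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(5):
            values = rng.normal(size=(30, 3))
            labels = rng.integers(0, 3, size=30)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(values, labels) == pytest.approx(
                silhouette_bruteforce(values, labels), abs=1e-10
            )

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="two clusters"):
            silhouette(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))


class TestCalinskiHarabasz:
    def test_hand_computed_two_pairs(self):
        # SSB = 100, SSW = 0.01, k = 2, n = 4 -> CH = 20000
        assert calinski_harabasz(FOUR_POINTS, FOUR_LABELS) == pytest.approx(20000.0)

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            values = rng.normal(size=(25, 4))
            labels = rng.integers(0, 3, size=25)
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_harabasz(values, labels) == pytest.approx(
                calinski_harabasz_bruteforce(values, labels), rel=1e-10
            )

    def test_increases_as_clumps_separate(self, rng):
        values, labels = _two_clumps(rng, sep=4.0)
        ch_values = []
        for extra in (0.0, 4.0, 8.0):
            shifted = values.copy()
            shifted[labels == 1] += extra
            ch_values.append(calinski_harabasz(shifted, labels))
        assert ch_values[0] < ch_values[1] < ch_values[2]

    def test_all_singletons_rejected(self, rng):
        with pytest.raises(ValueError, match="own cluster"):
            calinski_harabasz(rng.normal(size=(4, 2)), np.arange(4))


class TestCriteriaInvariances:
    def test_label_permutation_invariance(self, rng):
        values, labels = _two_clumps(rng)
        relabelled = 1 - labels
        assert silhouette(values, labels) == pytest.approx(
            silhouette(values, relabelled), abs=1e-12)
        assert calinski_harabasz(values, labels) == pytest.approx(
            calinski_harabasz(values, relabelled), rel=1e-12)
        assert wss(values, labels) == pytest.approx(wss(values, relabelled), rel=1e-12)


def _ranked_from(m: NPXMatrix, order: list[str]) -> RankedFeatures:
    table = pd.DataFrame({
        "median_abs_loading": np.linspace(1.0, 0.1, len(order)),
        "senescent": False,
    }, index=pd.Index(order, name="protein"))
    return RankedFeatures(table=table, selected_pc=1, n_bootstraps=1)


class TestForwardPanelSelection:
    def test_vacuous_threshold_keeps_entire_list(self, rng):
        values = rng.normal(size=(12, 5))
        m = NPXMatrix([f"p{i}" for i in range(12)], [f"G{j}" for j in range(5)], values)
        ranked = _ranked_from(m, m.protein_ids)
        result = forward_panel_selection(ranked, m, threshold=-1.0, seed=0,
                                         k_range=range(2, 4))
        assert result.panel == m.protein_ids

    def test_unreachable_threshold_reports_max(self, rng):
        values = rng.normal(size=(20, 4))
        m = NPXMatrix([f"p{i}" for i in range(20)], [f"G{j}" for j in range(4)], values)
        ranked = _ranked_from(m, m.protein_ids)
        with pytest.raises(ValueError, match="max achieved"):
            forward_panel_selection(ranked, m, threshold=0.99, seed=0)

    def test_recovers_planted_panel_on_cohort(self, complete_cohort):
        complete, clinical, labels, truth = complete_cohort
        ranked = bootstrap_rank(complete, clinical.data["severity"],
                                senescence=labels, n_bootstraps=100, seed=5)
        result = forward_panel_selection(ranked, complete, seed=6)
        assert result.chosen_k == 2
        assert len(set(result.panel) & truth.informative_proteins) >= 8
        assert result.step_trace["silhouette"].between(-1, 1).all()
        # WSS non-increasing in k for the final panel
        wss_by_k = result.criteria["wss"]
        assert (wss_by_k.diff().dropna() <= 1e-6 * wss_by_k.max()).all()

    def test_deterministic_given_seed(self, complete_cohort):
        complete, clinical, labels, _ = complete_cohort
        ranked = bootstrap_rank(complete, clinical.data["severity"],
                                senescence=labels, n_bootstraps=50, seed=8)
        r1 = forward_panel_selection(ranked, complete, seed=9)
        r2 = forward_panel_selection(ranked, complete, seed=9)
        assert r1.panel == r2.panel
        assert r1.chosen_k == r2.chosen_k
        pd.testing.assert_frame_equal(r1.step_trace, r2.step_trace)


class TestNameCohorts:
    def _assignment_and_matrix(self, means=(3.0, 5.0)):
        values = np.vstack([
            np.full((4, 2), means[0]),
            np.full((4, 2), means[1]),
        ])
        m = NPXMatrix([f"p{i}" for i in range(8)], ["A", "B"], values)
        assign = kmeans(values, 2, seed=0, patient_ids=m.patient_ids)
        return assign, m

    def test_higher_panel_mean_is_severe(self):
        assign, m = self._assignment_and_matrix()
        assign = name_cohorts(assign, m, ["A", "B"])
        cohorts = assign.cohort_series()
        severe_patients = set(cohorts[cohorts == "severe-cluster"].index)
        assert severe_patients == {f"p{i}" for i in range(4, 8)}

    def test_tie_breaks_to_cluster_zero_mild(self, rng):
        values = rng.normal(size=(8, 2))
        m = NPXMatrix([f"p{i}" for i in range(8)], ["A", "B"], values)
        assign = kmeans(values, 2, seed=1, patient_ids=m.patient_ids)
        # force identical panel means by overwriting the frame values
        m2 = NPXMatrix(m.patient_ids, m.protein_ids, np.full((8, 2), 4.0))
        assign = name_cohorts(assign, m2, ["A", "B"])
        assert assign.cohort_names[0] == "mild-cluster"
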