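import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from sendotype.pseudobulk import (
    CellAnnotations,
    PseudobulkMatrix,
    aggregate,
    cpm,
    pseudobulk_de,
    read_counts_mtx,
    remove_low_expression,
    tpm,
    write_counts_mtx,
)
from sendotype.synthetic_data import generate_counts


def _annotations(samples, celltypes, conditions):
    frame = pd.DataFrame({
        "sample_id": samples,
        "cell_type": celltypes,
        "condition": conditions,
    }, index=pd.Index([f"cell{i}" for i in range(len(samples))], name="barcode"))
    return CellAnnotations(frame)


class TestAggregate:
    def test_hand_summation(self):
        counts = np.array([[1, 2], [3, 4]])
        ann = _annotations(["s1", "s1"], ["immune", "immune"], ["case", "case"])
        pb = aggregate(counts, ann, ["g1", "g2"])
        np.testing.assert_array_equal(pb.counts.loc[("s1", "immune")], [4, 6])

    def test_cell_order_irrelevant(self, rng):
        counts = rng.integers(0, 20, size=(8, 5))
        samples = ["s1"] * 4 + ["s2"] * 4
        ctypes = ["immune", "epithelial"] * 4
        conds = ["case"] * 4 + ["control"] * 4
        ann = _annotations(samples, ctypes, conds)
        pb1 = aggregate(counts, ann, [f"g{j}" for j in range(5)])
        perm = rng.permutation(8)
        ann2 = CellAnnotations(ann.data.iloc[perm])
        pb2 = aggregate(counts[perm], ann2, [f"g{j}" for j in range(5)])
        pd.testing.assert_frame_equal(pb1.counts, pb2.counts)

    def test_matches_bruteforce_totals(self, rng):
        counts, genes, ann, _ = generate_counts(n_samples=3, n_genes=40,
                                                cells_per_sample=30, de_genes=0,
                                                lfc=0.0, seed=5)
        pb = aggregate(counts, ann, genes)
        dense = counts.toarray()
        for (sample, ctype), row in pb.counts.iterrows():
            mask = ((ann.data["sample_id"] == sample)
                    & (ann.data["cell_type"] == ctype)).to_numpy()
            np.testing.assert_array_equal(row.to_numpy(), dense[mask].sum(axis=0))

    def test_split_cell_invariance_of_cpm(self):
        counts = np.array([[4, 8, 2]])
        split = np.array([[2, 4, 1], [2, 4, 1]])
        ann1 = _annotations(["s1"], ["immune"], ["case"])
        ann2 = _annotations(["s1", "s1"], ["immune", "immune"], ["case", "case"])
        pb1 = aggregate(counts, ann1, list("abc"))
        pb2 = aggregate(split, ann2, list("abc"))
        pd.testing.assert_frame_equal(pb1.cpm_frame(), pb2.cpm_frame())


class TestNormalisation:
    def test_cpm_arithmetic(self):
        np.testing.assert_allclose(cpm(np.array([1, 1, 2])),
                                   [250000, 250000, 500000])

    def test_tpm_equal_lengths_is_cpm(self):
        counts = np.array([3.0, 5.0, 2.0])
        np.testing.assert_allclose(tpm(counts, np.full(3, 1500.0)), cpm(counts))

    def test_tpm_length_normalisation(self):
        np.testing.assert_allclose(tpm(np.array([1.0, 1.0]), np.array([1.0, 2.0])),
                                   [2e6 / 3, 1e6 / 3])

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero row"):
            cpm(np.zeros(4))

    def test_row_sums_are_one_million(self, rng):
        counts, genes, ann, _ = generate_counts(n_samples=2, n_genes=50,
                                                cells_per_sample=20, de_genes=0,
                                                lfc=0.0, seed=3)
        pb = aggregate(counts, ann, genes)
        lengths = pd.Series(rng.uniform(300, 3000, size=50), index=genes)
        pb = PseudobulkMatrix(counts=pb.counts, condition=pb.condition,
                              gene_lengths=lengths)
        sums = pb.tpm_frame().sum(axis=1)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)
        np.testing.assert_allclose(pb.cpm_frame().sum(axis=1), 1e6, rtol=1e-6)


class TestRemoveLowExpression:
    def _pb(self, totals):
        rows = {}
        for i, total in enumerate(totals):
            rows[(f"s{i}", "immune")] = np.array([total // 2, total - total // 2])
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=["g1", "g2"])
        frame.index = pd.MultiIndex.from_tuples(frame.index,
                                                names=["sample_id", "cell_type"])
        condition = pd.Series({f"s{i}": "case" for i in range(len(totals))})
        return PseudobulkMatrix(counts=frame, condition=condition)

    def test_threshold_zero_is_identity(self):
        pb = self._pb([100, 200])
        out, removed = remove_low_expression(pb, min_total=0)
        assert removed == []
        pd.testing.assert_frame_equal(out.counts, pb.counts)

    def test_threshold_above_all_rejected(self):
        with pytest.raises(ValueError, match="every sample"):
            remove_low_expression(self._pb([100, 200]), min_total=10_000)

    def test_starved_biopsies_removed_like_study_cohort(self, rng):
        # 15 case + 18 control samples; 3 case samples planted with ~1000x
        # lower depth -> 12 + 18 remain
        counts, genes, ann, _ = generate_counts(
            n_samples=33, n_genes=60, n_celltypes=3, injury_fraction=15 / 33,
            de_genes=0, lfc=0.0, cells_per_sample=40, seed=9,
        )
        dense = counts.toarray().astype(float)
        starved = {"S01", "S02", "S03"}
        starved_cells = ann.data["sample_id"].isin(starved).to_numpy()
        dense[starved_cells] = np.floor(dense[starved_cells] / 1000.0)
        pb = aggregate(dense, ann, genes)
        filtered, removed = remove_low_expression(pb, min_total=5000)
        assert set(removed) == starved
        remaining = filtered.condition.value_counts().to_dict()
        assert remaining == {"control": 18, "case": 12}


class TestPseudobulkDe:
    def test_swapping_conditions_negates_fold_changes(self):
        counts, genes, ann, _ = generate_counts(n_samples=6, n_genes=40,
                                                cells_per_sample=30, de_genes=5,
                                                lfc=1.5, seed=21)
        pb = aggregate(counts, ann, genes)
        de1 = pseudobulk_de(pb)
        de2 = pseudobulk_de(pb, case="control", control="case")
        for ctype in de1:
            merged = de1[ctype].join(de2[ctype], lsuffix="_a", rsuffix="_b")
            np.testing.assert_allclose(merged["log2_fc_a"], -merged["log2_fc_b"],
                                       atol=1e-10)

    def test_recovers_planted_injury_genes(self):
        counts, genes, ann, planted = generate_counts(seed=2)
        pb = aggregate(counts, ann, genes)
        de = pseudobulk_de(pb)
        hits = set()
        for table in de.values():
            hits |= set(table.index[table["adj_p"] < 0.05])
        assert len(hits & planted) / len(planted) >= 0.6


class TestMtxIo:
    def test_round_trip_and_determinism(self, tmp_path):
        counts, genes, ann, _ = generate_counts(n_samples=2, n_genes=30,
                                                cells_per_sample=15, de_genes=0,
                                                lfc=0.0, seed=4)
        write_counts_mtx(counts, genes, ann, tmp_path / "a")
        back, genes_back, ann_back = read_counts_mtx(
            tmp_path / "a" / "counts.mtx", tmp_path / "a" / "genes.tsv",
            tmp_path / "a" / "barcodes.tsv", tmp_path / "a" / "annotations.tsv")
        assert genes_back == genes
        np.testing.assert_array_equal(back.toarray(), counts.toarray())
        pd.testing.assert_frame_equal(ann_back.data, ann.data)
        # identical seed -> identical bytes
        counts2, genes2, ann2, _ = generate_counts(n_samples=2, n_genes=30,
                                                   cells_per_sample=15, de_genes=0,
                                                   lfc=0.0, seed=4)
        write_counts_mtx(counts2, genes2, ann2, tmp_path / "b")
        assert (tmp_path / "a" / "counts.mtx").read_bytes() == \
            (tmp_path / "b" / "counts.mtx").read_bytes()
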