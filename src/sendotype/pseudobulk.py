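"""Cell-type-resolved pseudobulk aggregation and transcriptomic validation DE.

Single-cell counts (cells x genes, MatrixMarket sparse + TSV annotations) are
summed per (sample, cell type) so each biopsy contributes one datapoint per
cell type.  Rows are normalised to counts-per-million and — when gene lengths
are available — transcripts-per-million; samples with starved cell-type rows
are removed; differential expression between condition groups runs the same
Welch engine as the proteomic stage, on log2(TPM + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .differential_expression import bh_adjust, welch_t_test

logger = logging.getLogger("sendotype")

__all__ = [
    "CellAnnotations",
    "PseudobulkMatrix",
    "read_counts_mtx",
    "write_counts_mtx",
    "aggregate",
    "cpm",
    "tpm",
    "remove_low_expression",
    "pseudobulk_de",
]

ANNOTATION_COLUMNS = ("sample_id", "cell_type", "condition")


@dataclass
class CellAnnotations:
    """Per-cell annotations: sample of origin, assigned cell type, condition."""

    data: pd.DataFrame  # index: cell barcode; columns: sample_id, cell_type, condition

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"annotations missing columns: {missing}")
        if self.data[list(ANNOTATION_COLUMNS)].isna().any().any():
            raise ValueError("every cell must be fully annotated")
        per_sample = self.data.groupby("sample_id")["condition"].nunique()
        if (per_sample > 1).any():
            bad = list(per_sample[per_sample > 1].index)
            raise ValueError(f"samples mapped to multiple conditions: {bad}")

    @property
    def sample_condition(self) -> pd.Series:
        return self.data.groupby("sample_id")["condition"].first()


@dataclass
class PseudobulkMatrix:
    """(sample, cell_type) x gene summed counts with CPM/TPM transforms."""

    counts: pd.DataFrame  # MultiIndex (sample_id, cell_type) rows, gene columns
    condition: pd.Series  # sample_id -> condition
    gene_lengths: pd.Series | None = None  # gene -> length in bases

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.counts.index.get_level_values(0)))

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.counts.index.get_level_values(1)))

    def cpm_frame(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("zero row totals; remove starved rows first")
        return self.counts.div(totals, axis=0) * 1e6

    def tpm_frame(self) -> pd.DataFrame:
        if self.gene_lengths is None:
            logger.warning("tpm_frame: no gene lengths supplied; falling back to CPM")
            return self.cpm_frame()
        lengths = self.gene_lengths.loc[self.counts.columns].to_numpy(dtype=float)
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        rates = self.counts / lengths
        totals = rates.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("zero row totals; remove starved rows first")
        return rates.div(totals, axis=0) * 1e6


def read_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    annotations_path: str | Path,
) -> tuple[sparse.csr_matrix, list[str], CellAnnotations]:
    """Read cells x genes MatrixMarket counts plus TSV gene/barcode/annotation files."""
    counts = sparse.csr_matrix(sio.mmread(str(mtx_path)))
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    barcodes = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    if counts.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"counts shape {counts.shape} does not match {len(barcodes)} barcodes x "
            f"{len(genes)} genes"
        )
    ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
    ann = ann.loc[barcodes]
    return counts, genes, CellAnnotations(ann)


def write_counts_mtx(
    counts: sparse.spmatrix,
    genes: list[str],
    annotations: CellAnnotations,
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(out / "counts.mtx"), sparse.coo_matrix(counts))
    (out / "genes.tsv").write_text("\n".join(genes) + "\n", encoding="utf-8")
    (out / "barcodes.tsv").write_text("\n".join(annotations.data.index) + "\n",
                                      encoding="utf-8")
    annotations.data.to_csv(out / "annotations.tsv", sep="\t", index_label="barcode")


def aggregate(
    counts: sparse.spmatrix | np.ndarray,
    annotations: CellAnnotations,
    genes: list[str],
    gene_lengths: pd.Series | None = None,
) -> PseudobulkMatrix:
    """Sum expression counts per gene within each (sample, cell type) group.

    Each sample contributes one pseudobulk row per cell type it has cells
    for; (sample, cell type) pairs with zero cells are simply absent (logged).
    """
    mat = sparse.csr_matrix(counts)
    ann = annotations.data
    if mat.shape[0] != len(ann):
        raise ValueError("counts rows must match annotated cells")
    groups = ann.groupby(["sample_id", "cell_type"], sort=True).indices
    rows = {}
    for (sample, ctype), idx in groups.items():
        rows[(sample, ctype)] = np.asarray(mat[idx].sum(axis=0)).ravel()
    n_expected = len(ann["sample_id"].unique()) * len(ann["cell_type"].unique())
    if len(rows) < n_expected:
        logger.info("aggregate: %d (sample, cell_type) pairs had no cells and were omitted",
                    n_expected - len(rows))
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["sample_id", "cell_type"])
    frame = frame.sort_index()
    return PseudobulkMatrix(counts=frame, condition=annotations.sample_condition,
                            gene_lengths=gene_lengths)


def cpm(row_counts: np.ndarray) -> np.ndarray:
    """Counts-per-million scaling of one pseudobulk row."""
    row = np.asarray(row_counts, dtype=float)
    total = row.sum()
    if total == 0:
        raise ValueError("zero row total; remove starved rows first")
    return row / total * 1e6


def tpm(row_counts: np.ndarray, gene_lengths: np.ndarray | None = None) -> np.ndarray:
    """Transcripts-per-million: length-normalised rates rescaled to one million.

    Without gene lengths TPM is not computable from counts alone; the row
    falls back to CPM with a warning (equal lengths cancel exactly).
    """
    row = np.asarray(row_counts, dtype=float)
    if gene_lengths is None:
        logger.warning("tpm: no gene lengths supplied; falling back to CPM")
        return cpm(row)
    lengths = np.asarray(gene_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = row / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("zero row total; remove starved rows first")
    return rate / total * 1e6


def remove_low_expression(
    pb: PseudobulkMatrix,
    min_total: int = 50_000,
) -> tuple[PseudobulkMatrix, list[str]]:
    """Drop samples with any cell-type row totalling fewer than ``min_total`` counts."""
    totals = pb.counts.sum(axis=1)
    starved = sorted(set(
        sample for (sample, _), total in totals.items() if total < min_total
    ))
    if starved:
        logger.info("remove_low_expression: removing samples %s (row total < %d)",
                    ",".join(starved), min_total)
    keep = [s for s in pb.samples if s not in starved]
    if not keep:
        raise ValueError("low-expression filter removed every sample")
    filtered = pb.counts.loc[pb.counts.index.get_level_values(0).isin(keep)]
    return (
        PseudobulkMatrix(counts=filtered, condition=pb.condition.loc[keep],
                         gene_lengths=pb.gene_lengths),
        starved,
    )


def pseudobulk_de(
    pb: PseudobulkMatrix,
    case: str = "case",
    control: str = "control",
) -> dict[str, pd.DataFrame]:
    """Welch DE on log2(TPM + 1) per gene, within each cell type.

    log2 fold change is case mean minus control mean on the log2(TPM + 1)
    scale; BH adjustment is applied per cell type.  Returns a table per cell
    type, sorted by p.
    """
    tpm_frame = pb.tpm_frame()
    results: dict[str, pd.DataFrame] = {}
    for ctype in pb.cell_types:
        block = tpm_frame.xs(ctype, level="cell_type")
        cond = pb.condition.loc[block.index]
        x = np.log2(block[cond == case].to_numpy() + 1.0)
        y = np.log2(block[cond == control].to_numpy() + 1.0)
        if x.shape[0] < 2 or y.shape[0] < 2:
            logger.warning("pseudobulk_de: cell type %s lacks >=2 samples per group; skipped",
                           ctype)
            continue
        rows = []
        for j, gene in enumerate(block.columns):
            t, df, p = welch_t_test(x[:, j], y[:, j])
            rows.append({
                "gene": gene,
                "log2_fc": float(x[:, j].mean() - y[:, j].mean()),
                "t_stat": t,
                "df": df,
                "p_value": p,
            })
        table = pd.DataFrame(rows).set_index("gene")
        table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
        results[ctype] = table.sort_values(["p_value", "gene"], kind="mergesort")
    if not results:
        raise ValueError("no cell type had at least two samples per condition")
    return results
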