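"""Core data containers, file readers/writers, and the completeness QC gate.

The discovery pipeline consumes a wide NPX matrix (patients x proteins,
log2-scale Olink-style values with missingness), a per-patient clinical
table, a plain-text list of senescence-associated protein symbols, and a
GMT gene-set collection.  Everything downstream (ranking, clustering,
differential expression) assumes a complete matrix, so QC filtering and
median imputation live here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("sendotype")

__all__ = [
    "NPXMatrix",
    "ClinicalTable",
    "SenescenceLabels",
    "GeneSetCollection",
    "read_npx_matrix",
    "write_npx_matrix",
    "qc_filter_proteins",
    "impute_missing",
    "read_clinical",
    "read_labels",
    "read_gmt",
]

CLINICAL_COLUMNS = (
    "age",
    "sex",
    "weight",
    "bmi",
    "systolic_bp",
    "diastolic_bp",
    "diabetes",
    "hypercholesterolaemia",
    "cvd",
    "cause_of_ckd",
    "creatinine_baseline",
    "creatinine_followup",
    "egfr_baseline",
    "egfr_followup",
    "urea",
    "severity",
)

SEVERITY_LEVELS = ("mild", "moderate", "severe")


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what} ids: {', '.join(dups)}")


@dataclass
class NPXMatrix:
    """Patients x proteins log2-scale expression with an explicit missing mask.

    ``values`` is a float matrix; entries where ``missing_mask`` is True are
    NaN.  Wherever the mask is False the value must be finite.
    """

    patient_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if n != len(self.patient_ids) or p != len(self.protein_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.patient_ids)} patients, {len(self.protein_ids)} proteins)"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values")
        _check_unique(self.patient_ids, "patient")
        _check_unique(self.protein_ids, "protein")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite values outside the missing mask")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def to_frame(self) -> pd.DataFrame:
        """Patients-as-rows DataFrame with NaN where values are missing."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.patient_ids, columns=self.protein_ids)

    def subset_proteins(self, proteins: list[str]) -> "NPXMatrix":
        idx = [self.protein_ids.index(p) for p in proteins]
        return NPXMatrix(
            patient_ids=list(self.patient_ids),
            protein_ids=list(proteins),
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
        )

    def complete_values(self) -> np.ndarray:
        if self.missing_mask.any():
            raise ValueError("matrix still has missing values; run impute_missing first")
        return self.values


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates, keyed by patient id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing required columns: {', '.join(missing)}")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        _check_unique(self.data.index, "patient")
        if (pd.to_numeric(self.data["age"], errors="coerce") <= 0).any():
            raise ValueError("ages must be positive")
        for col in ("creatinine_baseline", "creatinine_followup"):
            if (pd.to_numeric(self.data[col], errors="coerce") <= 0).any():
                raise ValueError(f"{col} must be positive")
        if self.data["severity"].isna().any():
            raise ValueError("severity must be present for every patient")
        bad = set(self.data["severity"]) - set(SEVERITY_LEVELS)
        if bad:
            raise ValueError(f"unknown severity levels: {sorted(bad)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, m: NPXMatrix) -> "ClinicalTable":
        """Inner-join ordering against an NPX matrix (clinical ids must cover it)."""
        missing = [p for p in m.patient_ids if p not in self.data.index]
        if missing:
            raise ValueError(f"clinical table lacks NPX patients: {missing[:5]}")
        return ClinicalTable(self.data.loc[m.patient_ids])


@dataclass(frozen=True)
class SenescenceLabels:
    """Symbols differentially expressed in at least one cellular-senescence model."""

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("senescence label set is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class GeneSetCollection:
    """term_id -> (description, member symbols), e.g. parsed from a Broad GMT."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_npx_matrix(
    path: str | Path,
    orientation: Literal["patients_as_rows", "proteins_as_rows"] = "patients_as_rows",
    sep: str | None = None,
) -> NPXMatrix:
    """Read a delimited NPX matrix; empty cells or "NA" denote missing.

    Returns the matrix in patients-as-rows orientation regardless of the
    input orientation.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    with path.open(encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r]
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header line plus at least one data row")
    col_ids = [c.strip() for c in rows[0][1:]]
    row_ids = [r[0].strip() for r in rows[1:]]
    _check_unique(col_ids, "column")
    _check_unique(row_ids, "row")
    values = np.full((len(row_ids), len(col_ids)), np.nan)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(col_ids) + 1:
            raise ValueError(f"{path}: row {row_ids[i]!r} has {len(row) - 1} cells, "
                             f"expected {len(col_ids)}")
        for j, raw in enumerate(row[1:]):
            text = raw.strip()
            if text == "" or text.upper() == "NA":
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {text!r} at row {row_ids[i]!r}, column {col_ids[j]!r}"
                ) from None
    if orientation == "proteins_as_rows":
        values = values.T
        patients, proteins = col_ids, row_ids
    elif orientation == "patients_as_rows":
        patients, proteins = row_ids, col_ids
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return NPXMatrix(patient_ids=patients, protein_ids=proteins, values=values)


def write_npx_matrix(m: NPXMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write patients-as-rows with 6 significant digits; missing cells as NA."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["patient_id", *m.protein_ids])
        for i, pid in enumerate(m.patient_ids):
            row = [pid]
            for j in range(m.n_proteins):
                row.append("NA" if m.missing_mask[i, j] else format(m.values[i, j], ".6g"))
            writer.writerow(row)


def qc_filter_proteins(m: NPXMatrix, min_fraction: float = 0.80) -> NPXMatrix:
    """Retain proteins observed in strictly more than ``min_fraction`` of patients.

    The threshold is exclusive ("over 80%"): a protein seen in exactly 80% of
    patients is dropped.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    observed_frac = 1.0 - m.missing_mask.mean(axis=0)
    keep = observed_frac > min_fraction
    kept = [p for p, k in zip(m.protein_ids, keep) if k]
    dropped = [p for p, k in zip(m.protein_ids, keep) if not k]
    if not kept:
        raise ValueError(
            "QC removed every protein; review min_fraction against the cohort's missingness"
        )
    logger.info(
        "qc_filter_proteins: retained %d, dropped %d proteins (min_fraction=%.3g)",
        len(kept), len(dropped), min_fraction,
    )
    if dropped:
        logger.debug("qc_filter_proteins dropped: %s", ",".join(dropped))
    return m.subset_proteins(kept)


def impute_missing(m: NPXMatrix, method: str = "per_protein_median") -> NPXMatrix:
    """Fill missing entries with the per-protein median of observed values."""
    if method != "per_protein_median":
        raise ValueError(f"unknown imputation method {method!r}")
    values = m.values.copy()
    mask = m.missing_mask
    fully_missing = [p for p, col in zip(m.protein_ids, mask.T) if col.all()]
    if fully_missing:
        raise ValueError(
            f"proteins fully missing (should have been QC-filtered): {fully_missing[:5]}"
        )
    for j in range(m.n_proteins):
        col_mask = mask[:, j]
        if col_mask.any():
            values[col_mask, j] = np.median(values[~col_mask, j])
    return NPXMatrix(
        patient_ids=list(m.patient_ids),
        protein_ids=list(m.protein_ids),
        values=values,
        missing_mask=np.zeros_like(mask),
    )


def read_clinical(path: str | Path, sep: str | None = None) -> ClinicalTable:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in ("diabetes", "hypercholesterolaemia", "cvd"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False, "true": True,
                                   "false": False, "1": True, "0": False}).fillna(df[col])
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path: str | Path, sep: str = ",") -> None:
    t.data.to_csv(Path(path), sep=sep, index_label="patient_id", encoding="utf-8")


def read_labels(path: str | Path, casefold: bool = False) -> SenescenceLabels:
    """One symbol per line; blank lines ignored; duplicates deduplicated with a warning.

    Symbol matching downstream is exact (case-sensitive); ``casefold=True``
    upper-cases symbols on read for joins across identifier conventions.
    """
    lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    symbols = [ln.upper() if casefold else ln for ln in lines if ln]
    if len(symbols) != len(set(symbols)):
        logger.warning("read_labels: duplicate symbols in %s were deduplicated", path)
    return SenescenceLabels(frozenset(symbols))


def write_labels(labels: SenescenceLabels, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(labels.symbols)) + "\n", encoding="utf-8")


def read_gmt(path: str | Path, casefold: bool = False) -> GeneSetCollection:
    """Broad-dialect GMT: term <tab> description <tab> member symbols."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >=3 tab-separated fields")
        term, desc, *members = fields
        members = [mem.upper() if casefold else mem for mem in members if mem]
        if term in sets:
            raise ValueError(f"duplicate GMT term {term!r} at line {lineno}")
        sets[term] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for term, (desc, members) in collection.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
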