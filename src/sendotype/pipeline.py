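"""End-to-end sendotype discovery orchestration.

Runs QC -> imputation -> bootstrap-PCA ranking -> silhouette-constrained
panel selection -> k-means endotyping -> differential expression -> clinical
contrasts -> renal-trajectory regressions -> pathway over-representation,
writing every table as CSV plus a JSON summary and a reproducibility
manifest (input hashes, stage seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical_analysis import (
    clinical_long_format,
    cohort_clinical_compare,
    trajectory_regression,
)
from .differential_expression import de_table, heatmap_table, volcano_table
from .feature_ranking import bootstrap_rank, zscore_columns
from .io_model import (
    ClinicalTable,
    GeneSetCollection,
    NPXMatrix,
    SenescenceLabels,
    impute_missing,
    qc_filter_proteins,
)
from .panel_selection import forward_panel_selection, kmeans, name_cohorts
from .pathway_ora import de_to_query, ora

logger = logging.getLogger("sendotype")

__all__ = ["DiscoveryConfig", "DiscoveryResult", "run_discover"]


@dataclass(frozen=True)
class DiscoveryConfig:
    qc_min_fraction: float = 0.80
    n_bootstraps: int = 500
    n_pc_candidates: int = 10
    silhouette_threshold: float = 0.5
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 25
    de_alpha: float = 0.05
    heatmap_top_n: int = 25
    seed: int = 0


@dataclass
class DiscoveryResult:
    panel: list[str]
    chosen_k: int
    cohorts: pd.Series  # patient id -> cohort name
    ranked: pd.DataFrame
    de: pd.DataFrame
    clinical_contrasts: pd.DataFrame
    trajectories: pd.DataFrame
    enrichment: pd.DataFrame | None
    summary: dict


def _stage_seeds(root_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    names = ("bootstrap", "panel", "cluster")
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_discover(
    npx: NPXMatrix,
    clinical: ClinicalTable,
    labels: SenescenceLabels,
    gene_sets: GeneSetCollection | None = None,
    config: DiscoveryConfig = DiscoveryConfig(),
    out_dir: str | Path | None = None,
    input_paths: dict[str, Path] | None = None,
) -> DiscoveryResult:
    """Full discovery run on in-memory inputs; writes a report bundle if
    ``out_dir`` is given."""
    seeds = _stage_seeds(config.seed)

    clinical = clinical.aligned_to(npx)
    qc = qc_filter_proteins(npx, min_fraction=config.qc_min_fraction)
    complete = impute_missing(qc)

    severity = clinical.data["severity"]
    ranked = bootstrap_rank(
        complete,
        severity_labels=severity,
        senescence=labels,
        n_bootstraps=config.n_bootstraps,
        n_candidates=config.n_pc_candidates,
        seed=seeds["bootstrap"],
    )
    panel_result = forward_panel_selection(
        ranked,
        complete,
        k_range=range(config.k_min, config.k_max + 1),
        threshold=config.silhouette_threshold,
        n_restarts=config.n_restarts,
        seed=seeds["panel"],
    )
    panel = panel_result.panel
    panel_values = zscore_columns(complete.subset_proteins(panel).values)
    assignment = kmeans(
        panel_values, panel_result.chosen_k, n_restarts=config.n_restarts,
        seed=seeds["cluster"], patient_ids=complete.patient_ids,
    )
    assignment = name_cohorts(assignment, complete, panel)
    cohorts = assignment.cohort_series()

    de = de_table(complete, cohorts, labels)
    contrasts = cohort_clinical_compare(clinical, cohorts)

    traj_rows = []
    frame = complete.to_frame()
    for outcome_name, outcome_col in (("egfr_followup", "egfr_followup"),
                                      ("creatinine_followup", "creatinine_followup")):
        outcome = clinical.data[outcome_col].to_numpy(dtype=float)
        for protein in panel:
            fit = trajectory_regression(frame[protein].to_numpy(), outcome)
            traj_rows.append({
                "protein": protein, "outcome": outcome_name,
                "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
            })
    trajectories = pd.DataFrame(traj_rows)

    enrichment = None
    if gene_sets is not None:
        query = de_to_query(de, alpha=config.de_alpha)
        if query:
            enrichment = ora(query, gene_sets, universe=set(complete.protein_ids))
        else:
            logger.warning("run_discover: no significant DE symbols; ORA skipped")

    cohort_sizes = cohorts.value_counts().to_dict()
    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_patients": complete.n_patients,
        "n_proteins_post_qc": complete.n_proteins,
        "panel": panel,
        "panel_size": len(panel),
        "chosen_k": panel_result.chosen_k,
        "selected_pc": ranked.selected_pc,
        "cohort_sizes": {str(k): int(v) for k, v in cohort_sizes.items()},
        "top_de_hits": de.index[:10].tolist(),
        "n_de_significant": int((de["adj_p"] < config.de_alpha).sum()),
    }

    result = DiscoveryResult(
        panel=panel, chosen_k=panel_result.chosen_k, cohorts=cohorts,
        ranked=ranked.table, de=de, clinical_contrasts=contrasts,
        trajectories=trajectories, enrichment=enrichment, summary=summary,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranked.table.to_csv(out / "ranked_features.csv")
        panel_result.step_trace.to_csv(out / "panel_step_trace.csv", index=False)
        panel_result.criteria.to_csv(out / "cluster_criteria.csv")
        cohorts.to_frame().to_csv(out / "cluster_assignments.csv")
        de.to_csv(out / "differential_expression.csv")
        volcano_table(de).to_csv(out / "volcano.csv")
        heatmap_table(de, complete, cohorts, top_n=config.heatmap_top_n).to_csv(
            out / "heatmap.csv")
        contrasts.to_csv(out / "clinical_contrasts.csv")
        clinical_long_format(clinical, cohorts).to_csv(out / "clinical_long.csv",
                                                       index=False)
        trajectories.to_csv(out / "trajectory_regressions.csv", index=False)
        if enrichment is not None:
            enrichment.to_csv(out / "pathway_enrichment.csv")
        manifest = {
            "package_version": __version__,
            "config": asdict(config),
            "stage_seeds": seeds,
            "inputs": {
                name: _hash_file(Path(p)) for name, p in (input_paths or {}).items()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True),
                                           encoding="utf-8")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True),
                                          encoding="utf-8")
    return result
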