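"""End-to-end orchestration of the copy-number evolution analysis.

Stage order: read -> harmonize -> QC -> phase -> distance matrices ->
trees + split support -> star/clock tests (BH-corrected across patients)
-> landscape embedding -> TH/CE indices -> median dichotomization ->
survival comparison.  All randomness flows from a single seed; the same
seed and inputs give byte-identical outputs.

The cohort-statistics stages can also be run from a precomputed
per-patient indices table (``run_from_indices``), which is how the
packaged clinical fixture is analysed without raw genomic data.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distance import distance_matrix, phase_patient
from .landscape import ce_index, dichotomize_by_median, embed_landscape, th_index
from .phylo import bh_adjust, build_tree, clock_test, split_support, star_topology_test
from .profiles import PatientDataset, apply_qc_filters, read_cohort
from .survival import bootstrap_robustness, km_median, logrank_test

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort", "run_from_indices"]


@dataclass(frozen=True)
class PipelineConfig:
    segment_table: str | Path | None = None
    metadata_table: str | Path | None = None
    clinical_table: str | Path | None = None
    out_dir: str | Path = "results"
    min_cellularity: float = 0.5
    min_samples: int = 3
    strict_cellularity: bool = False
    exhaustive_threshold: int = 12
    n_support_replicates: int = 100
    n_null: int = 10_000
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.min_cellularity <= 1.0:
            raise ValueError("min_cellularity must lie in [0, 1]")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def analyze_cohort(
    cohort: list[PatientDataset], config: PipelineConfig, out_dir: Path | None = None
) -> dict:
    """Genomic stages for a QC-passed cohort; returns per-patient results."""
    per_patient: dict[str, dict] = {}
    for ds in cohort:
        stage = "phase"
        try:
            phased = phase_patient(ds, exhaustive_threshold=config.exhaustive_threshold)
            stage = "distance"
            dm = distance_matrix(phased)
            stage = "tree"
            tree = build_tree(dm)
            stage = "support"
            support = split_support(
                phased, n_replicates=config.n_support_replicates, seed=config.seed
            )
            stage = "star_test"
            star = star_topology_test(dm)
            stage = "clock_test"
            clock = clock_test(tree)
            stage = "landscape"
            emb = embed_landscape(dm)
            th = th_index(emb, ds.records)
            ce = ce_index(emb, n_null=config.n_null, seed=config.seed)
        except Exception as err:
            raise RuntimeError(f"patient {ds.patient_id}: stage {stage!r} failed: {err}") from err
        # annotate supports on the tree copy for output
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            allt = frozenset(t.name for t in tree.tips())
            key = min(side, allt - side, key=lambda s: (len(s), sorted(s)))
            if key in support:
                node.name = f"{support[key]:.2f}"
        per_patient[ds.patient_id] = {
            "phased": phased,
            "dm": dm,
            "tree": tree,
            "support": support,
            "star": star,
            "clock": clock,
            "th_index": th,
            "ce_index": ce,
            "n_samples": len(ds.profiles),
        }
        if out_dir is not None:
            dm.write_tsv(out_dir / f"{ds.patient_id}_distances.tsv")
            (out_dir / f"{ds.patient_id}.nwk").write_text(str(tree))
    # BH correction across patients
    pids = list(per_patient)
    star_adj = bh_adjust([per_patient[p]["star"].p for p in pids])
    clock_adj = bh_adjust([per_patient[p]["clock"].p for p in pids])
    for p, sa, ca in zip(pids, star_adj, clock_adj):
        per_patient[p]["star"] = dataclasses.replace(per_patient[p]["star"], p_adj=sa)
        per_patient[p]["clock"] = dataclasses.replace(per_patient[p]["clock"], p_adj=ca)
    return per_patient


def _survival_report(indices: pd.DataFrame, clinical: pd.DataFrame, config: PipelineConfig) -> dict:
    """Dichotomize by median CE and compare survival between the groups."""
    merged = indices.merge(clinical, on="patient_id", how="inner")
    merged = merged[np.isfinite(merged.ce_index.astype(float))].reset_index(drop=True)
    groups = dichotomize_by_median(dict(zip(merged.patient_id, merged.ce_index.astype(float))))
    merged["ce_group"] = merged.patient_id.map(groups)
    report: dict = {"n_patients": int(len(merged)), "groups": groups}
    for endpoint, dur_col, ev_col in (("PFS", "pfs_days", "pfs_event"), ("OS", "os_days", "os_event")):
        low = merged[merged.ce_group == "CE-low"]
        high = merged[merged.ce_group == "CE-high"]
        entry = {
            "median_low_months": km_median(low[dur_col], low[ev_col]),
            "median_high_months": km_median(high[dur_col], high[ev_col]),
            "n_low": int(len(low)),
            "n_high": int(len(high)),
        }
        if len(low) and len(high):
            entry["logrank_p"] = logrank_test(
                merged[dur_col], merged[ev_col], (merged.ce_group == "CE-high").astype(int)
            )
            boot = bootstrap_robustness(
                merged.assign(ce_index=merged.ce_index.astype(float)),
                dur_col,
                ev_col,
                ce_col="ce_index",
                n_boot=config.n_boot,
                seed=config.seed,
            )
            entry["bootstrap"] = {
                "frac_significant": boot.frac_significant,
                "median_hr": boot.median_hr,
                "hr_ci": list(boot.hr_ci),
                "n_single_group": boot.n_single_group,
            }
        report[endpoint] = entry
    return report


def run_from_indices(
    indices: pd.DataFrame, clinical: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Cohort-statistics stages from a precomputed per-patient index table."""
    config = config or PipelineConfig()
    return _survival_report(indices, clinical, config)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.segment_table, config.metadata_table)
    cohort, qc = apply_qc_filters(
        cohort,
        min_cellularity=config.min_cellularity,
        min_samples=config.min_samples,
        strict_cellularity=config.strict_cellularity,
    )
    qc.to_frame().to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    result: dict = {"qc": qc, "per_patient": {}, "survival": None}
    if cohort:
        per_patient = analyze_cohort(cohort, config, out_dir=out)
        result["per_patient"] = per_patient
        rows = []
        for pid, r in per_patient.items():
            rows.append(
                {
                    "patient_id": pid,
                    "n_samples": r["n_samples"],
                    "th_index": r["th_index"],
                    "ce_index": r["ce_index"],
                    "star_chi2": r["star"].chi2,
                    "star_df": r["star"].df,
                    "star_p": r["star"].p,
                    "star_p_adj": r["star"].p_adj,
                    "clock_p": r["clock"].p,
                    "clock_p_adj": r["clock"].p_adj,
                }
            )
        indices = pd.DataFrame(rows)
        indices.to_csv(out / "cohort_indices.tsv", sep="\t", index=False, float_format="%.6g")
        if config.clinical_table is not None:
            clinical = pd.read_csv(config.clinical_table, sep="\t", dtype={"patient_id": str})
            try:
                surv = _survival_report(indices, clinical, config)
            except ValueError:
                surv = None  # too few evaluable patients
            result["survival"] = surv
            (out / "survival.json").write_text(json.dumps(surv, indent=1, sort_keys=True))
    log = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "min_cellularity": config.min_cellularity,
        "min_samples": config.min_samples,
        "n_patients_retained": qc.n_patients_retained,
        "n_samples_retained": qc.n_samples_retained,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return result
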