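"""Config-driven orchestration and result-surface export.

``run_pipeline`` drives the whole analysis from one config (synthetic
cohort XOR files on disk), writes every result surface — profiles,
assignments, scores, metric reports, the Sankey cross-tabulation, habitat
label maps — and a structured run log with versions, seeds and a config
hash.  Two runs with the same config produce byte-identical CSV/JSON
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterAssignment
from .cohort import CohortConfig, write_cohort
from .io import (DEFAULT_HU_WINDOW, DEFAULT_TARGET_SPACING, load_case,
                 load_clinical_table, save_label_map)
from .model import HabitatAnalysis, HabitatAnalysisResults

logger = logging.getLogger("habistrat")


@dataclasses.dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input source.

    Either ``synthetic`` holds a :class:`CohortConfig`, or ``manifest``
    points at a cohort directory manifest written by ``write_cohort``.
    """

    synthetic: Optional[CohortConfig] = None
    manifest: Optional[str] = None
    output_dir: str = "habistrat_out"
    radius: int = 2
    k_habitats: int = 8
    patient_k: int = 2
    target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    max_voxels_per_patient: int = 2000
    use_pca: bool = True
    variance_kept: float = 0.95
    bootstrap_B: int = 200
    seed: int = 0
    write_voxel_tables: bool = False
    write_habitat_maps: bool = True
    write_cohort_files: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest is None):
            raise ValueError("exactly one of synthetic/manifest must be set")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            sd = dataclasses.asdict(self.synthetic)
            sd["cluster_mixtures"] = [list(map(float, m))
                                      for m in self.synthetic.cluster_mixtures]
            sd["archetypes"] = [dataclasses.asdict(a)
                                for a in self.synthetic.archetypes]
            d["synthetic"] = sd
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            sd = dict(d["synthetic"])
            if sd.get("archetypes") is not None:
                from .cohort import HabitatArchetype
                sd["archetypes"] = tuple(HabitatArchetype(**a)
                                         for a in sd["archetypes"])
            if sd.get("cluster_mixtures") is not None:
                sd["cluster_mixtures"] = tuple(np.asarray(m)
                                               for m in sd["cluster_mixtures"])
            for k in ("tumor_size_range", "spacing"):
                if sd.get(k) is not None:
                    sd[k] = tuple(sd[k])
            d["synthetic"] = CohortConfig(**sd)
        for k in ("target_spacing", "hu_window"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _load_cases_from_manifest(manifest_path: str | Path):
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    records = load_clinical_table(root / manifest["clinical"])
    rec_by_id = {r.patient_id: r for r in records}
    cases, ordered = [], []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        if pid not in rec_by_id:
            raise ValueError(f"patient {pid} in manifest but not in clinical table")
        image, mask = load_case(root / entry["image"], root / entry["mask"])
        cases.append((image, mask))
        ordered.append(rec_by_id[pid])
    return cases, ordered


# ---------------------------------------------------------------------------
# Sankey cross-tabulation


@dataclasses.dataclass
class SankeyTable:
    """CRS category x habitat cluster x TBS zone patient counts."""

    table: pd.DataFrame        # columns: crs_category, cluster, tbs_zone, count
    crs_to_cluster: pd.DataFrame
    cluster_to_tbs: pd.DataFrame
    n_complete: int
    n_incomplete: int


def sankey_crosstab(score_table: pd.DataFrame,
                    assignment: ClusterAssignment) -> SankeyTable:
    """Cross-tabulate patients over CRS category, cluster and TBS zone.

    Patients missing a score are tallied separately, never silently
    dropped; score/assignment id mismatches are an error listing orphans.
    """
    sc_ids = set(score_table["patient_id"])
    as_ids = set(assignment.assignments["patient_id"])
    orphans = sorted(sc_ids ^ as_ids)
    if orphans:
        raise ValueError(f"scores/assignment patient mismatch: {orphans}")
    merged = score_table.merge(assignment.assignments, on="patient_id")
    complete = merged.dropna(subset=["crs_category", "cluster", "tbs_zone"])
    n_incomplete = len(merged) - len(complete)
    counts = (complete.groupby(["crs_category", "cluster", "tbs_zone"],
                               observed=True)
              .size().reset_index(name="count")
              .sort_values(["crs_category", "cluster", "tbs_zone"])
              .reset_index(drop=True))
    crs_to_cluster = (complete.groupby(["crs_category", "cluster"],
                                       observed=True)
                      .size().reset_index(name="count")
                      .sort_values(["crs_category", "cluster"])
                      .reset_index(drop=True))
    cluster_to_tbs = (complete.groupby(["cluster", "tbs_zone"], observed=True)
                      .size().reset_index(name="count")
                      .sort_values(["cluster", "tbs_zone"])
                      .reset_index(drop=True))
    return SankeyTable(counts, crs_to_cluster, cluster_to_tbs,
                       n_complete=len(complete), n_incomplete=n_incomplete)


# ---------------------------------------------------------------------------
# Run


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> HabitatAnalysisResults:
    """Execute the full analysis and write the artifact directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.synthetic is not None:
            analysis = HabitatAnalysis.from_synthetic(
                config.synthetic, radius=config.radius,
                patient_k=config.patient_k,
                target_spacing=config.target_spacing,
                hu_window=config.hu_window,
                max_voxels_per_patient=config.max_voxels_per_patient,
                use_pca=config.use_pca, variance_kept=config.variance_kept,
                bootstrap_B=config.bootstrap_B,
                keep_voxel_tables=config.write_voxel_tables)
            if config.write_cohort_files:
                write_cohort(analysis.cases, analysis.truth,
                             outdir / "cohort", config.synthetic)
        else:
            cases, records = _load_cases_from_manifest(config.manifest)
            analysis = HabitatAnalysis(
                cases, records, radius=config.radius,
                k_habitats=config.k_habitats, patient_k=config.patient_k,
                target_spacing=config.target_spacing,
                hu_window=config.hu_window,
                max_voxels_per_patient=config.max_voxels_per_patient,
                use_pca=config.use_pca, variance_kept=config.variance_kept,
                bootstrap_B=config.bootstrap_B, seed=config.seed,
                keep_voxel_tables=config.write_voxel_tables)
        logger.info("loaded %d cases", len(analysis.cases))
        stage = "fit"
        results = analysis.fit()
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    # result surfaces
    results.profiles.to_csv(outdir / "habitat_profiles.csv", index=False)
    results.assignment.assignments.to_csv(outdir / "cluster_assignments.csv",
                                          index=False)
    results.assignment.diagnostics.to_csv(outdir / "cluster_diagnostics.csv",
                                          index=False)
    results.score_table.to_csv(outdir / "prognostic_scores.csv", index=False)
    results.markers.to_csv(outdir / "risk_markers.csv", index=False)
    results.summary().to_csv(outdir / "model_comparison.csv", index=False)
    results.dictionary.to_json(outdir / "habitat_dictionary.json")
    if results.truth is not None:
        results.truth.to_csv(outdir / "truth.csv", index=False)

    per_habitat, (chi2, dof, p) = results.compare_habitats()
    per_habitat.to_csv(outdir / "habitat_comparison.csv", index=False)

    sankey = sankey_crosstab(results.score_table, results.assignment)
    sankey.table.to_csv(outdir / "sankey_threeway.csv", index=False)
    sankey.crs_to_cluster.to_csv(outdir / "sankey_crs_to_cluster.csv",
                                 index=False)
    sankey.cluster_to_tbs.to_csv(outdir / "sankey_cluster_to_tbs.csv",
                                 index=False)

    metrics_payload = {
        "metrics": results.metrics,
        "logrank": {ep: {"chi2": v[0], "dof": v[1], "p": v[2]}
                    for ep, v in results.logrank.items()},
        "habitat_distribution_global_test": {"chi2": chi2, "dof": dof, "p": p},
        "cluster_sizes": results.cluster_sizes(),
        "chosen_k": results.assignment.chosen_k,
    }
    (outdir / "metric_report.json").write_text(
        json.dumps(metrics_payload, indent=1, sort_keys=True,
                   default=_json_default))

    if config.write_habitat_maps:
        maps_dir = outdir / "habitat_maps"
        maps_dir.mkdir(exist_ok=True)
        for pid, lab in results.habitat_maps.items():
            geom = results.map_geometry[pid]
            save_label_map(lab, geom["spacing"],
                           maps_dir / f"{pid}_habitats.nii.gz")
    if config.write_voxel_tables and results.voxel_table is not None:
        # per-voxel tables can be very large; export is opt-in
        results.voxel_table.to_csv(outdir / "voxel_features.csv", index=False)

    run_log = {
        "habistrat_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": len(analysis.cases),
        "stages": ["standardize", "voxel_features", "normalize",
                   "habitat_dictionary", "profiles", "patient_clustering",
                   "scores", "survival_metrics", "sankey"],
    }
    (outdir / "run_log.json").write_text(
        json.dumps(run_log, indent=1, sort_keys=True))
    config.to_json(outdir / "config.json")
    return results
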