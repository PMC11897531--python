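"""Top-level modelling objects: fit the habitat analysis, hold the results.

:class:`HabitatAnalysis` plays the role of a statsmodels-style model object:
it is constructed from the per-patient cases (image + mask + clinical
record), ``fit()`` runs standardization, voxel feature extraction, the
cohort habitat dictionary, patient clustering and the prognostic scores, and
returns a :class:`HabitatAnalysisResults` carrying the estimates, the
model-comparison metrics per endpoint and a ``summary()`` table mirroring
the C-index / IBS comparison layout.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, features, scores, survival
from .cohort import CohortConfig, SyntheticCase, generate_cohort
from .io import (DEFAULT_HU_WINDOW, DEFAULT_TARGET_SPACING, ENDPOINTS,
                 PatientRecord, standardize_volume)

MODEL_NAMES = ("crs", "tbs", "habitat")
AUC_YEARS = tuple(range(1, 11))
NRI_IDI_HORIZON_MONTHS = 60.0


def _risk_markers(score_df: pd.DataFrame,
                  assignment: clustering.ClusterAssignment) -> pd.DataFrame:
    """Scalar risk markers per model (higher = worse prognosis)."""
    merged = score_df.merge(assignment.assignments, on="patient_id")
    return pd.DataFrame({
        "patient_id": merged["patient_id"],
        "crs": merged["crs_points"].astype(float),
        "tbs": merged["tbs_value"].astype(float),
        "habitat": (merged["cluster"] == 1).astype(float),
        "crs_group": merged["crs_category"],
        "tbs_group": merged["tbs_zone"],
        "habitat_group": merged["cluster"].map(lambda c: f"cluster_{c}"),
    })


def _group_km_predictions(groups: pd.Series, time: np.ndarray,
                          event: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Predicted S(t) per subject from the KM curve of the subject's group.

    This is the model-as-marker convention: each comparator model predicts
    through its own risk strata.
    """
    surv = np.empty((len(groups), len(grid)))
    for g in groups.unique():
        sel = (groups == g).to_numpy()
        curve = survival.kaplan_meier(time[sel], event[sel])
        surv[sel] = curve.evaluate(grid)[None, :]
    return surv


def evaluate_models(markers: pd.DataFrame, time, event,
                    auc_years: Sequence[int] = AUC_YEARS,
                    nri_idi_t: float = NRI_IDI_HORIZON_MONTHS,
                    bootstrap_B: int = 200, seed: int = 0) -> dict:
    """Head-to-head comparison of CRS, TBS and the habitat model.

    Per model: Harrell's C and IPCW IBS with percentile bootstrap 95%
    intervals, cumulative/dynamic AUC at yearly horizons; pairwise
    continuous NRI and IDI at ``nri_idi_t`` months (risks taken as
    group-KM event probabilities at that horizon).
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    n = len(time)
    t_max = min(120.0, float(time[event == 1].max())) if event.any() else 120.0
    grid = survival.make_prediction_grid(time, event, t_max)

    report: dict = {"n": n, "events": int(event.sum()),
                    "auc_definition": "cumulative/dynamic (IPCW)",
                    "nri_idi_horizon_months": nri_idi_t, "models": {}}
    surv_at_horizon: dict[str, np.ndarray] = {}
    for m in MODEL_NAMES:
        risk = markers[m].to_numpy()
        groups = markers[f"{m}_group"]

        def c_fn(idx, risk=risk):
            return survival.concordance_index(risk[idx], time[idx], event[idx])

        def ibs_fn(idx, groups=groups):
            sm = _group_km_predictions(groups.iloc[idx], time[idx], event[idx],
                                       grid)
            return survival.integrated_brier_score(sm, grid, time[idx],
                                                   event[idx], t_max)

        c_pt, c_lo, c_hi = survival.bootstrap_ci(c_fn, n, B=bootstrap_B,
                                                 seed=seed)
        i_pt, i_lo, i_hi = survival.bootstrap_ci(ibs_fn, n, B=bootstrap_B,
                                                 seed=seed + 1)
        auc = {}
        for yr in auc_years:
            t = 12.0 * yr
            try:
                auc[yr] = survival.time_dependent_auc(risk, time, event, t)
            except ValueError:
                auc[yr] = None
        surv_at_horizon[m] = _group_km_predictions(
            groups, time, event, np.array([nri_idi_t]))[:, 0]
        report["models"][m] = {
            "c_index": c_pt, "c_index_ci": [c_lo, c_hi],
            "ibs": i_pt, "ibs_ci": [i_lo, i_hi],
            "auc_by_year": auc,
        }

    pairwise = {}
    for new, old in (("habitat", "crs"), ("habitat", "tbs"), ("tbs", "crs")):
        risk_new = 1.0 - surv_at_horizon[new]
        risk_old = 1.0 - surv_at_horizon[old]
        try:
            pairwise[f"{new}_vs_{old}"] = {
                "nri": survival.nri(risk_old, risk_new, time, event, nri_idi_t),
                "idi": survival.idi(risk_old, risk_new, time, event, nri_idi_t),
            }
        except ValueError:
            pairwise[f"{new}_vs_{old}"] = {"nri": None, "idi": None}
    report["pairwise"] = pairwise
    return report


@dataclasses.dataclass
class HabitatAnalysisResults:
    """Fitted estimates, diagnostics and model-comparison metrics."""

    dictionary: clustering.HabitatDictionary
    normalization: features.NormalizationParams
    profiles: pd.DataFrame
    assignment: clustering.ClusterAssignment
    score_table: pd.DataFrame
    markers: pd.DataFrame
    metrics: dict[str, dict]
    logrank: dict[str, tuple[float, int, float]]
    habitat_maps: dict[str, np.ndarray]
    map_geometry: dict[str, dict]
    records: list[PatientRecord]
    truth: Optional[pd.DataFrame] = None
    voxel_table: Optional[pd.DataFrame] = None

    def summary(self) -> pd.DataFrame:
        """Model x endpoint table of C-index and IBS (Table-2 layout)."""
        rows = []
        for ep, rep in self.metrics.items():
            for m in MODEL_NAMES:
                entry = rep["models"][m]
                rows.append({
                    "endpoint": ep, "model": m,
                    "c_index": round(entry["c_index"], 4),
                    "c_index_95ci": tuple(round(v, 4)
                                          for v in entry["c_index_ci"]),
                    "ibs": round(entry["ibs"], 4),
                    "ibs_95ci": tuple(round(v, 4) for v in entry["ibs_ci"]),
                })
        return pd.DataFrame(rows)

    def compare_habitats(self) -> tuple[pd.DataFrame, tuple[float, int, float]]:
        """Between-cluster habitat-distribution tests."""
        return clustering.compare_habitat_distribution(self.assignment,
                                                       self.profiles)

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.assignment.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


class HabitatAnalysis:
    """End-to-end habitat analysis over a cohort of cases.

    Parameters
    ----------
    cases : list of (image, mask) tuples or SyntheticCase
    records : clinical records aligned with cases (omitted when cases are
        SyntheticCase objects, which carry their own record)
    """

    def __init__(self, cases, records: Optional[list[PatientRecord]] = None, *,
                 radius: int = features.DEFAULT_RADIUS,
                 k_habitats: int = clustering.DEFAULT_K_HABITATS,
                 patient_k: int = 2,
                 target_spacing=DEFAULT_TARGET_SPACING,
                 hu_window=DEFAULT_HU_WINDOW,
                 max_voxels_per_patient: int =
                 clustering.DEFAULT_MAX_VOXELS_PER_PATIENT,
                 use_pca: bool = True, variance_kept: float = 0.95,
                 bootstrap_B: int = 200, seed: int = 0,
                 truth: Optional[pd.DataFrame] = None,
                 keep_voxel_tables: bool = False):
        if records is None:
            if not all(isinstance(c, SyntheticCase) for c in cases):
                raise ValueError("records required unless cases are synthetic")
            records = [c.record for c in cases]
        if len(cases) != len(records):
            raise ValueError("cases and records must align")
        self.cases = cases
        self.records = records
        self.radius = radius
        self.k_habitats = k_habitats
        self.patient_k = patient_k
        self.target_spacing = tuple(target_spacing)
        self.hu_window = tuple(hu_window)
        self.max_voxels_per_patient = max_voxels_per_patient
        self.use_pca = use_pca
        self.variance_kept = variance_kept
        self.bootstrap_B = bootstrap_B
        self.seed = seed
        self.truth = truth
        self.keep_voxel_tables = keep_voxel_tables

    @classmethod
    def from_synthetic(cls, config: CohortConfig, **kwargs) -> "HabitatAnalysis":
        cases, truth = generate_cohort(config)
        kwargs.setdefault("k_habitats", config.k_habitats)
        kwargs.setdefault("seed", config.seed)
        return cls(cases, truth=truth, **kwargs)

    def _case_pair(self, case):
        if isinstance(case, SyntheticCase):
            return case.image, case.mask
        return case  # (image, mask) tuple

    def fit(self, compute_metrics: bool = True) -> HabitatAnalysisResults:
        """Run the full analysis.

        ``compute_metrics=False`` skips the bootstrap model-comparison
        metrics (clustering, scores and log-rank tests are still computed)
        — useful for replicate studies where only cluster recovery and
        group separation are scored.
        """
        # per-patient standardization + voxel features
        tables = []
        std_masks = {}
        map_geometry = {}
        for case, record in zip(self.cases, self.records):
            image, mask = self._case_pair(case)
            std_img, std_msk = standardize_volume(image, mask,
                                                  self.target_spacing,
                                                  self.hu_window)
            tab = features.extract_voxel_features(std_img, std_msk,
                                                  radius=self.radius,
                                                  hu_window=self.hu_window,
                                                  patient_id=record.patient_id)
            tables.append(tab)
            std_masks[record.patient_id] = std_msk
            map_geometry[record.patient_id] = {
                "shape": std_msk.shape, "spacing": std_msk.spacing}
        pooled = pd.concat(tables, ignore_index=True)

        norm = features.fit_normalization(pooled)
        pooled_norm = features.apply_normalization(pooled, norm)
        dictionary = clustering.fit_habitat_model(
            pooled_norm, K=self.k_habitats, seed=self.seed,
            max_voxels_per_patient=self.max_voxels_per_patient,
            normalization=norm)

        profiles_rows = []
        habitat_maps = {}
        offset = 0
        for tab, record in zip(tables, self.records):
            pid = record.patient_id
            norm_tab = pooled_norm.iloc[offset:offset + len(tab)]
            offset += len(tab)
            labels = clustering.assign_habitats(norm_tab, dictionary)
            profiles_rows.append(clustering.compute_habitat_profile(
                labels, tab["hu"].to_numpy(), self.k_habitats, pid))
            lab_map = np.zeros(std_masks[pid].shape, dtype=np.int16)
            lab_map[std_masks[pid].voxels.astype(bool)] = labels
            habitat_maps[pid] = lab_map
        profiles = pd.DataFrame(profiles_rows)

        os_events = np.array([r.endpoints["os"].event for r in self.records])
        assignment = clustering.cluster_patients(
            profiles, k=self.patient_k, seed=self.seed, use_pca=self.use_pca,
            variance_kept=self.variance_kept, event_indicator=os_events)

        score_table = scores.score_cohort(self.records)
        markers = _risk_markers(score_table, assignment)
        # align markers/records order
        order = {pid: i for i, pid in enumerate(markers["patient_id"])}
        rec_sorted = sorted(self.records,
                            key=lambda r: order[r.patient_id])

        metrics = {}
        logrank = {}
        cluster_labels = markers["habitat"].to_numpy()
        for ep in ENDPOINTS:
            time = np.array([r.endpoints[ep].time for r in rec_sorted])
            event = np.array([r.endpoints[ep].event for r in rec_sorted])
            if compute_metrics:
                metrics[ep] = evaluate_models(markers, time, event,
                                              bootstrap_B=self.bootstrap_B,
                                              seed=self.seed)
            logrank[ep] = survival.logrank_test(time, event, cluster_labels)

        return HabitatAnalysisResults(
            dictionary=dictionary, normalization=norm, profiles=profiles,
            assignment=assignment, score_table=score_table, markers=markers,
            metrics=metrics, logrank=logrank, habitat_maps=habitat_maps,
            map_geometry=map_geometry, records=rec_sorted, truth=self.truth,
            voxel_table=pooled if self.keep_voxel_tables else None)
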