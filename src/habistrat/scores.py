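"""Comparator prognostic models: Tumor Burden Score and Clinical Risk Score.

TBS = sqrt(dmax^2 + n^2) where dmax is the largest liver metastasis diameter
in cm and n the lesion count; zones low/medium/high at the conventional
cut-offs 3 and 9.  The Fong-style CRS awards one point each for node-positive
primary, disease-free interval < 12 months (synchronous disease counts),
more than one metastasis, dmax > 5 cm and CEA > 200 ng/mL; 0-2 = low risk,
3-5 = high.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import pandas as pd

from .io import PatientRecord

TBS_CUTOFFS = (3.0, 9.0)
CRS_HIGH_THRESHOLD = 3
TBS_ZONES = ("low", "medium", "high")
CRS_CATEGORIES = ("low", "high")


def tumor_burden_score(dmax_cm: float, n_mets: int) -> float:
    """TBS = sqrt(dmax^2 + n^2); strictly increasing in both arguments."""
    if dmax_cm <= 0:
        raise ValueError(f"dmax_cm must be > 0, got {dmax_cm}")
    if n_mets < 1 or int(n_mets) != n_mets:
        raise ValueError(f"n_mets must be an integer >= 1, got {n_mets}")
    return math.hypot(dmax_cm, n_mets)


def tbs_zone(value: float, cutoffs: tuple[float, float] = TBS_CUTOFFS) -> str:
    """Left-closed zoning: low < c1 <= medium < c2 <= high."""
    if value <= 0:
        raise ValueError(f"TBS must be > 0, got {value}")
    low, high = cutoffs
    if value < low:
        return "low"
    if value < high:
        return "medium"
    return "high"


def clinical_risk_score(record: PatientRecord) -> tuple[int, str, bool]:
    """Fong-style CRS points, category and a CEA-completeness flag.

    Returns ``(points, category, cea_known)``.  A missing CEA scores 0 for
    that criterion (flagged, never imputed); all other criteria are
    mandatory and raise when absent.
    """
    for field in ("node_positive_primary", "synchronous", "n_metastases",
                  "dmax_cm"):
        if getattr(record, field, None) is None:
            raise ValueError(f"patient {record.patient_id}: missing mandatory "
                             f"covariate '{field}' for CRS")
    points = 0
    points += int(bool(record.node_positive_primary))
    points += int(bool(record.synchronous))  # interval < 12 months
    points += int(record.n_metastases > 1)
    points += int(record.dmax_cm > 5.0)
    cea_known = record.cea_ng_ml is not None
    if cea_known and record.cea_ng_ml > 200.0:
        points += 1
    category = "high" if points >= CRS_HIGH_THRESHOLD else "low"
    return points, category, cea_known


@dataclasses.dataclass(frozen=True)
class ScoreSet:
    patient_id: str
    tbs_value: float
    tbs_zone: str
    crs_points: int
    crs_category: str
    crs_cea_known: bool


def score_patient(record: PatientRecord,
                  tbs_cutoffs: tuple[float, float] = TBS_CUTOFFS) -> ScoreSet:
    tbs = tumor_burden_score(record.dmax_cm, record.n_metastases)
    points, category, cea_known = clinical_risk_score(record)
    return ScoreSet(record.patient_id, tbs, tbs_zone(tbs, tbs_cutoffs),
                    points, category, cea_known)


def score_cohort(records: list[PatientRecord],
                 tbs_cutoffs: tuple[float, float] = TBS_CUTOFFS,
                 ) -> pd.DataFrame:
    """Score every patient; one row per patient, CSV-friendly."""
    rows = [dataclasses.asdict(score_patient(r, tbs_cutoffs)) for r in records]
    df = pd.DataFrame(rows)
    df["crs_cea_known"] = df["crs_cea_known"].astype(int)
    return df
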