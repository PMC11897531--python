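"""Volume/mask I/O, grid standardization and the clinical table.

Images are contrast-enhanced CT volumes in Hounsfield units with anisotropic
voxel spacing; masks are binary tumor segmentations aligned to the image grid
(the VOI).  Heterogeneous acquisitions (slice thickness 2.5-7.5 mm, pixel
spacing ~0.6-1.0 mm) are standardized onto a common isotropic grid with a
fixed HU window before any feature extraction.

All grids are indexed (x, y, z) with spacing metadata; world origins are
carried through NIfTI affines but unused downstream.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_TARGET_SPACING = (1.0, 1.0, 1.0)
#: portal-venous liver window (HU)
DEFAULT_HU_WINDOW = (-100.0, 300.0)

ENDPOINTS = ("os", "dfs", "liver_dfs")

#: clinical CSV schema; cea_ng_ml is the only optional column
MANDATORY_COLUMNS = (
    "patient_id", "age", "sex", "major_comorbidity", "bmi",
    "node_positive_primary", "synchronous", "n_metastases", "dmax_cm",
    "bilobar", "extrahepatic", "chemo_before_resection", "preop_pve",
    "fibrosis_fraction",
    "time_os", "event_os", "time_dfs", "event_dfs",
    "time_liver_dfs", "event_liver_dfs",
)
OPTIONAL_COLUMNS = ("cea_ng_ml",)


@dataclasses.dataclass
class ImageVolume:
    """3D HU grid with voxel spacing (mm) and world origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("ImageVolume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclasses.dataclass
class SegmentationMask:
    """Binary tumor mask aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = (np.asarray(self.voxels) != 0).astype(np.uint8)
        if self.voxels.ndim != 3:
            raise ValueError("SegmentationMask requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


@dataclasses.dataclass(frozen=True)
class SurvivalEndpoint:
    """Observed follow-up time (months) and event indicator."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError(f"survival time must be finite and > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclasses.dataclass
class PatientRecord:
    """Clinical covariates and the three survival endpoints."""

    patient_id: str
    age: float
    sex: str
    major_comorbidity: bool
    bmi: float
    node_positive_primary: bool
    synchronous: bool
    n_metastases: int
    dmax_cm: float
    bilobar: bool
    extrahepatic: bool
    chemo_before_resection: bool
    preop_pve: bool
    fibrosis_fraction: float
    endpoints: dict[str, SurvivalEndpoint]
    cea_ng_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_metastases < 1:
            raise ValueError(f"{self.patient_id}: n_metastases must be >= 1")
        if self.dmax_cm <= 0:
            raise ValueError(f"{self.patient_id}: dmax_cm must be > 0")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError(f"{self.patient_id}: fibrosis_fraction outside [0,1]")
        missing = [e for e in ENDPOINTS if e not in self.endpoints]
        if missing:
            raise ValueError(f"{self.patient_id}: missing endpoints {missing}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_case(image: ImageVolume, mask: SegmentationMask,
              image_path: str | Path, mask_path: str | Path) -> None:
    """Write an image/mask pair as NIfTI-1 files."""
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32),
                             _affine(image.spacing, image.origin)),
             str(image_path))
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8),
                             _affine(mask.spacing, mask.origin)),
             str(mask_path))


def save_label_map(labels: np.ndarray, spacing: Sequence[float],
                   path: str | Path, origin: Sequence[float] = (0, 0, 0)) -> None:
    """Write an integer label volume (e.g. a habitat map) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(labels).astype(np.int16),
                             _affine(spacing, origin)), str(path))


def load_case(image_path: str | Path, mask_path: str | Path,
              spacing_tol: float = 1e-3) -> tuple[ImageVolume, SegmentationMask]:
    """Load an aligned image/mask NIfTI pair.

    The mask is binarized (any nonzero label becomes foreground).  Shape or
    spacing disagreement beyond ``spacing_tol`` mm, or an empty mask, is an
    error.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    img_data = np.asarray(img.dataobj, dtype=np.float64)
    msk_data = np.asarray(msk.dataobj)
    img_spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    msk_spacing = tuple(float(z) for z in msk.header.get_zooms()[:3])
    if img_data.shape != msk_data.shape or any(
            abs(a - b) > spacing_tol for a, b in zip(img_spacing, msk_spacing)):
        raise ValueError(
            "image/mask geometry mismatch: image "
            f"shape={img_data.shape} spacing={img_spacing}; mask "
            f"shape={msk_data.shape} spacing={msk_spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    volume = ImageVolume(img_data, img_spacing, origin)
    mask = SegmentationMask(msk_data, img_spacing, origin)
    if mask.n_foreground == 0:
        raise ValueError(f"mask {mask_path} has no foreground voxels")
    return volume, mask


# ---------------------------------------------------------------------------
# Standardization


def clip_hu(voxels: np.ndarray, hu_window: tuple[float, float]) -> np.ndarray:
    low, high = hu_window
    if not low < high:
        raise ValueError(f"hu_window must satisfy low < high, got {hu_window}")
    return np.clip(voxels, low, high)


def standardize_volume(volume: ImageVolume, mask: SegmentationMask,
                       target_spacing: Sequence[float] = DEFAULT_TARGET_SPACING,
                       hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
                       ) -> tuple[ImageVolume, SegmentationMask]:
    """Resample to ``target_spacing`` and clip HU to ``hu_window``.

    The image is trilinearly interpolated, the mask nearest-neighbour
    resampled so it stays binary.  Output voxel ``i`` samples the input at
    continuous index ``i * target / source`` along each axis (edge-clamped).
    """
    low, high = hu_window
    if not low < high:
        raise ValueError(f"hu_window must satisfy low < high, got {hu_window}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing must be positive")
    src = volume.spacing
    if np.allclose(src, target_spacing, atol=1e-9):
        out_img = ImageVolume(clip_hu(volume.voxels, hu_window), src, volume.origin)
        return out_img, SegmentationMask(mask.voxels.copy(), src, mask.origin)

    factors = [s / t for s, t in zip(src, target_spacing)]
    new_shape = tuple(max(1, int(round(n * f)))
                      for n, f in zip(volume.shape, factors))
    grids = np.meshgrid(*[np.arange(n) / f for n, f in zip(new_shape, factors)],
                        indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    img_out = ndimage.map_coordinates(volume.voxels.astype(np.float64), coords,
                                      order=1, mode="nearest").reshape(new_shape)
    msk_out = ndimage.map_coordinates(mask.voxels, coords, order=0,
                                      mode="nearest").reshape(new_shape)
    if msk_out.sum() == 0:
        raise ValueError(
            "resampling to spacing "
            f"{target_spacing} emptied the mask (tumor below resolution)")
    out_img = ImageVolume(clip_hu(img_out, hu_window), target_spacing, volume.origin)
    out_msk = SegmentationMask(msk_out, target_spacing, mask.origin)
    return out_img, out_msk


# ---------------------------------------------------------------------------
# Clinical table


def _as_bool(v) -> bool:
    return bool(int(v))


def load_clinical_table(csv_path: str | Path) -> list[PatientRecord]:
    """Parse the clinical CSV into typed :class:`PatientRecord` objects.

    Missing optional fields (CEA) stay absent — nothing is imputed.  Missing
    mandatory columns or non-positive survival times are hard errors.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing mandatory columns: {missing}")
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        endpoints = {}
        for ep in ENDPOINTS:
            t, e = float(row[f"time_{ep}"]), int(row[f"event_{ep}"])
            if not t > 0:
                raise ValueError(f"patient {pid}: non-positive time_{ep} = {t}")
            endpoints[ep] = SurvivalEndpoint(t, e)
        cea = None
        if "cea_ng_ml" in df.columns and pd.notna(row["cea_ng_ml"]):
            cea = float(row["cea_ng_ml"])
        records.append(PatientRecord(
            patient_id=pid,
            age=float(row["age"]),
            sex=str(row["sex"]),
            major_comorbidity=_as_bool(row["major_comorbidity"]),
            bmi=float(row["bmi"]),
            node_positive_primary=_as_bool(row["node_positive_primary"]),
            synchronous=_as_bool(row["synchronous"]),
            n_metastases=int(row["n_metastases"]),
            dmax_cm=float(row["dmax_cm"]),
            bilobar=_as_bool(row["bilobar"]),
            extrahepatic=_as_bool(row["extrahepatic"]),
            chemo_before_resection=_as_bool(row["chemo_before_resection"]),
            preop_pve=_as_bool(row["preop_pve"]),
            fibrosis_fraction=float(row["fibrosis_fraction"]),
            endpoints=endpoints,
            cea_ng_ml=cea,
        ))
    return records


def clinical_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the clinical CSV schema."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
            "major_comorbidity": int(r.major_comorbidity), "bmi": r.bmi,
            "node_positive_primary": int(r.node_positive_primary),
            "synchronous": int(r.synchronous),
            "n_metastases": r.n_metastases, "dmax_cm": r.dmax_cm,
            "bilobar": int(r.bilobar), "extrahepatic": int(r.extrahepatic),
            "chemo_before_resection": int(r.chemo_before_resection),
            "preop_pve": int(r.preop_pve),
            "fibrosis_fraction": r.fibrosis_fraction,
            "cea_ng_ml": r.cea_ng_ml,
        }
        for ep in ENDPOINTS:
            row[f"time_{ep}"] = r.endpoints[ep].time
            row[f"event_{ep}"] = r.endpoints[ep].event
        rows.append(row)
    return pd.DataFrame(rows)


def write_clinical_table(records: list[PatientRecord], csv_path: str | Path) -> None:
    clinical_frame(records).to_csv(csv_path, index=False)
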