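"""Per-voxel habitat features inside the VOI and their cohort normalization.

Five features per in-mask voxel: raw HU (intensity / portal-venous
enhancement), neighborhood mean and sample SD, 32-bin histogram entropy over
the HU window (texture), and a mask-restricted central-difference gradient
magnitude.  Neighborhoods are the (2r+1)^3 cube intersected with the mask —
background voxels never leak into tumor statistics.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import DEFAULT_HU_WINDOW, ImageVolume, SegmentationMask

FEATURE_COLUMNS = ("hu", "local_mean", "local_sd", "local_entropy",
                   "gradient_magnitude")
N_ENTROPY_BINS = 32
DEFAULT_RADIUS = 2


def _box_sum(arr: np.ndarray, size: int) -> np.ndarray:
    """Sum over the size^3 cube centered at each voxel, zero outside."""
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) \
        * float(size) ** 3


def extract_voxel_features(volume: ImageVolume, mask: SegmentationMask,
                           radius: int = DEFAULT_RADIUS,
                           hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
                           patient_id: str = "0") -> pd.DataFrame:
    """Compute the per-voxel feature table for all in-mask voxels.

    Returns one row per foreground voxel with columns ``patient_id``,
    ``i, j, k`` and :data:`FEATURE_COLUMNS`.  ``local_sd`` uses the sample
    (n-1) convention; entropy is base-2 over a fixed 32-bin grid spanning
    ``hu_window``; the gradient uses central differences where both
    neighbours are in the mask, one-sided differences at the mask boundary
    and 0 where neither neighbour is available.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    m = mask.voxels.astype(bool)
    if not m.any():
        raise ValueError("mask has no foreground voxels")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    img = volume.voxels.astype(np.float64)
    size = 2 * radius + 1
    mf = m.astype(np.float64)

    count = np.rint(_box_sum(mf, size))
    s1 = _box_sum(img * mf, size)
    s2 = _box_sum(img * img * mf, size)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(count > 0, s1 / count, 0.0)
        var = (s2 - s1 * s1 / np.maximum(count, 1)) / np.maximum(count - 1, 1)
    local_sd = np.sqrt(np.clip(var, 0.0, None))
    local_sd[count <= 1] = 0.0

    # histogram entropy on a fixed binning of the HU window
    low, high = hu_window
    bins = np.clip(((img - low) / (high - low) * N_ENTROPY_BINS).astype(int),
                   0, N_ENTROPY_BINS - 1)
    entropy = np.zeros_like(img)
    for b in range(N_ENTROPY_BINS):
        ind = (bins == b) & m
        if not ind.any():
            continue
        cb = np.rint(_box_sum(ind.astype(np.float64), size))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(count > 0, cb / count, 0.0)
        nz = p > 0
        entropy[nz] -= p[nz] * np.log2(p[nz])

    grad_sq = np.zeros_like(img)
    for axis, h in enumerate(volume.spacing):
        fwd_img = np.roll(img, -1, axis=axis)
        bwd_img = np.roll(img, 1, axis=axis)
        fwd_ok = np.roll(mf, -1, axis=axis) > 0
        bwd_ok = np.roll(mf, 1, axis=axis) > 0
        # roll wraps around; edge voxels have no neighbour on that side
        edge_lo = [slice(None)] * 3
        edge_lo[axis] = 0
        edge_hi = [slice(None)] * 3
        edge_hi[axis] = -1
        bwd_ok[tuple(edge_lo)] = False
        fwd_ok[tuple(edge_hi)] = False
        deriv = np.zeros_like(img)
        both = fwd_ok & bwd_ok
        deriv[both] = (fwd_img[both] - bwd_img[both]) / (2.0 * h)
        only_f = fwd_ok & ~bwd_ok
        deriv[only_f] = (fwd_img[only_f] - img[only_f]) / h
        only_b = bwd_ok & ~fwd_ok
        deriv[only_b] = (img[only_b] - bwd_img[only_b]) / h
        grad_sq += deriv ** 2
    gradient_magnitude = np.sqrt(grad_sq)

    idx = np.argwhere(m)
    table = pd.DataFrame({
        "patient_id": patient_id,
        "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
        "hu": img[m],
        "local_mean": local_mean[m],
        "local_sd": local_sd[m],
        "local_entropy": entropy[m],
        "gradient_magnitude": gradient_magnitude[m],
    })
    return table


# ---------------------------------------------------------------------------
# Cohort z-score normalization


@dataclasses.dataclass
class NormalizationParams:
    """Per-feature cohort mean/SD (sample convention) for z-scoring.

    Zero-variance features are dropped at fit time and recorded in
    ``dropped``; params fitted on a training cohort transfer verbatim to new
    patients.
    """

    features: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    dropped: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {"features": list(self.features),
                   "mean": self.mean.tolist(), "sd": self.sd.tolist(),
                   "dropped": list(self.dropped)}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["features"]), np.asarray(d["mean"]),
                   np.asarray(d["sd"]), tuple(d["dropped"]))


def fit_normalization(table: pd.DataFrame,
                      features: Sequence[str] = FEATURE_COLUMNS,
                      ) -> NormalizationParams:
    """Fit pooled-cohort z-score parameters (sample SD, n-1)."""
    if len(table) < 2:
        raise ValueError("need >= 2 pooled rows to fit normalization")
    kept, dropped, means, sds = [], [], [], []
    for f in features:
        col = table[f].to_numpy(dtype=np.float64)
        mu, sd = col.mean(), col.std(ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            dropped.append(f)
            warnings.warn(f"feature '{f}' has zero variance; dropped",
                          stacklevel=2)
            continue
        kept.append(f)
        means.append(mu)
        sds.append(sd)
    if not kept:
        raise ValueError("all features have zero variance")
    return NormalizationParams(tuple(kept), np.asarray(means), np.asarray(sds),
                               tuple(dropped))


def apply_normalization(table: pd.DataFrame, params: NormalizationParams,
                        ) -> pd.DataFrame:
    """Z-score the retained feature columns; passthrough for id columns."""
    out = table.copy()
    for f, mu, sd in zip(params.features, params.mean, params.sd):
        out[f] = (table[f].to_numpy(dtype=np.float64) - mu) / sd
    for f in params.dropped:
        if f in out.columns:
            out = out.drop(columns=f)
    return out
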