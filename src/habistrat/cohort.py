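"""Synthetic CRLM cohort generator with planted habitat structure.

Emulates the statistical structure the downstream analysis assumes: each
patient carries a latent cluster (1 = worse prognosis, 2 = better), the
cluster fixes a mixture over K intensity/texture-distinct habitat
archetypes, the tumor is a mildly perturbed ellipsoid whose interior is
tiled by Voronoi blobs carrying archetype labels, and the three survival
endpoints (OS, DFS, liver-specific DFS) follow a proportional-hazards
exponential model with a cluster-dependent log hazard ratio and
uniform-plus-administrative censoring.  The ground truth (cluster, habitat
map, linear predictors) is returned alongside so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .io import (ENDPOINTS, ImageVolume, PatientRecord, SegmentationMask,
                 SurvivalEndpoint, clinical_frame, save_case, save_label_map)

LIVER_BACKGROUND_HU = 100.0
LIVER_BACKGROUND_SD = 15.0


@dataclasses.dataclass(frozen=True)
class HabitatArchetype:
    """Intensity/texture phenotype of one planted habitat subregion."""

    label: int
    intensity_mean: float  # HU
    intensity_sd: float    # HU
    texture_scale: float   # voxel correlation length, >= 0

    def __post_init__(self) -> None:
        if self.intensity_sd <= 0:
            raise ValueError("intensity_sd must be > 0")
        if self.texture_scale < 0:
            raise ValueError("texture_scale must be >= 0")


def default_archetypes(k: int = 8) -> tuple[HabitatArchetype, ...]:
    """K intensity-distinct archetypes spanning the portal-venous HU range.

    Means spaced 30 HU apart from 20 HU upward, SD 8 HU (subregions are
    clearly intensity-distinct), with varied texture correlation lengths so
    local-SD/entropy features also differ by habitat.
    """
    scales = [0.0, 0.8, 1.5, 0.0, 1.0, 0.5, 1.5, 0.8]
    return tuple(HabitatArchetype(label=h + 1,
                                  intensity_mean=20.0 + 30.0 * h,
                                  intensity_sd=8.0,
                                  texture_scale=scales[h % len(scales)])
                 for h in range(k))


def default_cluster_mixtures(k: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Default habitat compositions of the two latent clusters.

    Cluster 1 (worse prognosis) is enriched in habitats 5, 7 and 8;
    cluster 2 in habitat 3.  Every habitat share differs between the
    clusters by at least 0.15 and the L1 overlap sum(min(m1, m2)) is 0.19,
    planting the near-ideal two-cluster separation the patient-level
    silhouette of real cohorts of this kind exhibits.
    """
    if k != 8:
        raise ValueError("default mixtures are defined for k=8")
    m1 = np.array([0.02, 0.18, 0.03, 0.18, 0.22, 0.02, 0.17, 0.18])
    m2 = np.array([0.18, 0.02, 0.40, 0.02, 0.04, 0.30, 0.02, 0.02])
    return m1, m2


@dataclasses.dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort scale of the source data (197 patients, two
    clusters of 96/101, ~58% male, mean largest-lesion size ~3.5 cm, slice
    thickness in the 2.5-7.5 mm range) with a doubled hazard in cluster 1
    and ~30% censoring.
    """

    n_patients: int = 197
    k_habitats: int = 8
    cluster_mixtures: Optional[tuple[np.ndarray, np.ndarray]] = None
    cluster_prevalence: float = 96.0 / 197.0
    tumor_size_range: tuple[float, float] = (15.0, 50.0)  # mm
    spacing: tuple[float, float, float] = (0.8, 0.8, 3.0)  # mm
    baseline_hazard: Optional[dict[str, float]] = None  # events/month
    log_hazard_ratio_cluster: float = math.log(2.0)
    censor_rate: float = 0.30
    horizon_months: float = 120.0
    seed: int = 0
    archetypes: Optional[tuple[HabitatArchetype, ...]] = None
    blob_size_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.cluster_prevalence < 1.0:
            raise ValueError("cluster_prevalence must lie in (0,1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0,1)")
        if self.cluster_mixtures is None:
            self.cluster_mixtures = default_cluster_mixtures(self.k_habitats)
        self.cluster_mixtures = tuple(
            np.asarray(m, dtype=np.float64) for m in self.cluster_mixtures)
        for m in self.cluster_mixtures:
            if len(m) != self.k_habitats:
                raise ValueError("mixture length != k_habitats")
            if abs(m.sum() - 1.0) > 1e-9 or np.any(m < 0):
                raise ValueError("mixtures must be probability vectors "
                                 "summing to 1 +- 1e-9")
        if self.baseline_hazard is None:
            self.baseline_hazard = {"os": 0.010, "dfs": 0.018,
                                    "liver_dfs": 0.014}
        if self.archetypes is None:
            self.archetypes = default_archetypes(self.k_habitats)


@dataclasses.dataclass
class SyntheticCase:
    patient_id: str
    image: ImageVolume
    mask: SegmentationMask
    true_habitat_map: np.ndarray  # 0 outside mask, 1..K inside
    record: PatientRecord


# ---------------------------------------------------------------------------
# Tumor image


def _smooth_unit_noise(shape, sigma: float, rng: np.random.Generator,
                       ) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit variance."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def generate_tumor_image(mixture, diameter_mm: float,
                         archetypes: Sequence[HabitatArchetype],
                         spacing: Sequence[float] = (1.0, 1.0, 1.0),
                         seed: int = 0,
                         blob_size_mm: float = 4.0,
                         margin_mm: float = 6.0,
                         ) -> tuple[ImageVolume, SegmentationMask, np.ndarray]:
    """Plant one ellipsoidal tumor composed of habitat blobs.

    The mask is a single connected, mildly boundary-perturbed ellipsoid; its
    interior is partitioned into Voronoi cells of seeded points (one seed
    per ``blob_size_mm``-cube of tumor volume, so the habitat blob scale is
    a tissue property independent of tumor size), and cells are assigned
    archetype labels by a greedy quota fill so blob-volume fractions track
    the requested mixture.  Voxel HU is drawn from the blob's archetype
    (mean + SD x unit-variance smoothed noise); outside the mask,
    liver-like background (100 HU) plus noise.

    Returns ``(image, mask, habitat_map)`` with the habitat map 0 outside
    the mask and the planted label 1..K inside.
    """
    mixture = np.asarray(mixture, dtype=np.float64)
    if abs(mixture.sum() - 1.0) > 1e-9 or np.any(mixture < 0):
        raise ValueError("mixture must be a probability vector summing to 1")
    if len(mixture) != len(archetypes):
        raise ValueError("mixture length != number of archetypes")
    spacing = tuple(float(s) for s in spacing)
    min_span = min(diameter_mm / s for s in spacing)
    if min_span < 5:
        raise ValueError(
            f"diameter {diameter_mm} mm spans fewer than 5 voxels along an "
            f"axis at spacing {spacing}; enlarge the tumor or refine spacing")
    rng = np.random.default_rng(seed)

    semi_mm = np.asarray([diameter_mm / 2.0] * 3) * rng.uniform(0.85, 1.15, 3)
    shape = tuple(int(np.ceil((2 * a + 2 * margin_mm) / s)) + 1
                  for a, s in zip(semi_mm, spacing))
    center = np.array([(n - 1) / 2.0 * s for n, s in zip(shape, spacing)])
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                         indexing="ij")
    q = sum(((c - mu) / a) ** 2
            for c, mu, a in zip(coords, center, semi_mm))
    # mild boundary perturbation via a smooth random field
    perturb = 0.10 * _smooth_unit_noise(shape, sigma=3.0, rng=rng)
    mask_arr = q <= 1.0 + perturb
    # keep the largest connected component so the VOI is a single lesion
    lab, n_comp = ndimage.label(mask_arr)
    if n_comp == 0:
        raise ValueError("perturbed ellipsoid produced an empty mask")
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n_comp + 1))
        mask_arr = lab == (1 + int(np.argmax(sizes)))

    voxel_mm = np.stack([c[mask_arr] for c in coords], axis=1)
    n_vox = len(voxel_mm)
    habitat_map = np.zeros(shape, dtype=np.int16)
    voxel_volume = float(np.prod(spacing))
    n_seeds = int(round(n_vox * voxel_volume / blob_size_mm ** 3))
    n_seeds = int(np.clip(n_seeds, 8, min(n_vox, 1500)))
    seed_idx = rng.choice(n_vox, size=n_seeds, replace=False)
    cell_of_voxel = np.empty(n_vox, dtype=np.int64)
    for start in range(0, n_vox, 20000):  # chunked nearest-seed scan
        block = voxel_mm[start:start + 20000]
        cell_of_voxel[start:start + 20000] = np.argmin(
            cdist(block, voxel_mm[seed_idx]), axis=1)
    cell_sizes = np.bincount(cell_of_voxel, minlength=n_seeds)
    # greedy quota fill: walk cells in random order, filling each habitat's
    # target volume share in turn
    order = rng.permutation(n_seeds)
    cell_label = np.zeros(n_seeds, dtype=np.int16)
    positive = np.where(mixture > 0)[0]  # zero-share habitats get no cells
    cum_targets = np.cumsum(mixture[positive]) * n_vox
    pos = 0
    filled = 0.0
    for cell in order:
        while pos < len(positive) - 1 and filled >= cum_targets[pos] - 1e-9:
            pos += 1
        cell_label[cell] = positive[pos] + 1
        filled += cell_sizes[cell]
    labels_in_mask = cell_label[cell_of_voxel]
    habitat_map[mask_arr] = labels_in_mask

    image = LIVER_BACKGROUND_HU + LIVER_BACKGROUND_SD * _smooth_unit_noise(
        shape, sigma=0.5, rng=rng)
    for arch in archetypes:
        sel = habitat_map == arch.label
        if not sel.any():
            continue
        field = _smooth_unit_noise(shape, sigma=arch.texture_scale, rng=rng)
        image[sel] = arch.intensity_mean + arch.intensity_sd * field[sel]

    volume = ImageVolume(image.astype(np.float32), spacing)
    mask = SegmentationMask(mask_arr, spacing)
    return volume, mask, habitat_map


# ---------------------------------------------------------------------------
# Survival simulation


def simulate_survival_endpoints(linear_predictor, baseline_hazard: float,
                                censor_rate: float, horizon_months: float,
                                seed: int = 0) -> pd.DataFrame:
    """Exponential proportional-hazards event times with independent censoring.

    Event time T_i ~ Exp(rate = baseline_hazard * exp(lp_i)).  Censoring is
    uniform on (0, horizon] with probability q, administrative at the
    horizon otherwise; q is solved in closed form so the expected censored
    fraction matches ``censor_rate`` (clamped at the administrative floor).
    Returns a frame with positive ``time`` and ``event`` in {0,1}.
    """
    lp = np.asarray(linear_predictor, dtype=np.float64)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    if baseline_hazard <= 0 or horizon_months <= 0:
        raise ValueError("baseline_hazard and horizon must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    rate = baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)

    lam_h = rate * horizon_months
    S_h = np.exp(-lam_h)                      # P(T > horizon)
    I_h = (1.0 - S_h) / lam_h                 # E[S(C)] for C ~ U(0, horizon]
    A, B = S_h.mean(), I_h.mean()
    q = 0.0 if censor_rate <= A else min(1.0, (censor_rate - A) / (B - A))
    C = np.full_like(T, horizon_months)
    uniform_mask = rng.uniform(size=len(T)) < q
    C[uniform_mask] = rng.uniform(0.0, horizon_months,
                                  size=int(uniform_mask.sum()))
    time = np.minimum(T, C)
    event = (T <= C).astype(np.int64)
    return pd.DataFrame({"time": time, "event": event})


# ---------------------------------------------------------------------------
# Cohort


def _sample_record(pid: str, cluster: int, rng: np.random.Generator,
                   dmax_cm: float, endpoints: dict[str, SurvivalEndpoint],
                   ) -> PatientRecord:
    """Clinical covariates roughly matching the study's Table-1 marginals."""
    cea = None
    if rng.uniform() > 0.15:  # ~15% missing CEA
        cea = float(np.exp(rng.normal(math.log(8.0), 1.5)))
    return PatientRecord(
        patient_id=pid,
        age=float(np.clip(rng.normal(59.5, 12.5), 18, 95)),
        sex="M" if rng.uniform() < 0.58 else "F",
        major_comorbidity=bool(rng.uniform() < 0.55),
        bmi=float(np.clip(rng.normal(27.3, 5.0), 15, 50)),
        node_positive_primary=bool(rng.uniform() < 0.35),
        synchronous=bool(rng.uniform() < 0.56),
        n_metastases=1 if rng.uniform() < 0.43 else 1 + int(rng.geometric(0.45)),
        dmax_cm=dmax_cm,
        bilobar=bool(rng.uniform() < 0.44),
        extrahepatic=bool(rng.uniform() < 0.08),
        chemo_before_resection=bool(rng.uniform() < 0.62),
        preop_pve=bool(rng.uniform() < 0.12),
        fibrosis_fraction=float(rng.beta(0.5, 2.2)),
        endpoints=endpoints,
        cea_ng_ml=cea,
    )


def generate_cohort(config: CohortConfig,
                    ) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Generate a full synthetic cohort and its ground truth.

    Cluster sizes are an exact configuration echo
    (round(prevalence * n) patients in cluster 1, seeded permutation).
    Returns the cases (image + mask + true habitat map + clinical record)
    and a truth frame with the latent cluster and per-endpoint linear
    predictors.
    """
    root = np.random.SeedSequence(config.seed)
    # independent streams: allocation, covariates, per-patient images, survival
    ss_alloc, ss_cov, ss_img, ss_surv = root.spawn(4)
    rng_alloc = np.random.default_rng(ss_alloc)
    rng_cov = np.random.default_rng(ss_cov)
    n = config.n_patients
    n1 = int(round(config.cluster_prevalence * n))
    clusters = np.full(n, 2, dtype=np.int64)
    clusters[rng_alloc.permutation(n)[:n1]] = 1

    # survival first (vectorized over the cohort per endpoint)
    lp = {ep: config.log_hazard_ratio_cluster * (clusters == 1).astype(float)
          for ep in ENDPOINTS}
    surv_seeds = ss_surv.generate_state(len(ENDPOINTS)) % (2 ** 31)
    endpoint_frames = {
        ep: simulate_survival_endpoints(lp[ep], config.baseline_hazard[ep],
                                        config.censor_rate,
                                        config.horizon_months,
                                        seed=int(surv_seeds[i]))
        for i, ep in enumerate(ENDPOINTS)}

    lo_mm, hi_mm = config.tumor_size_range
    img_seeds = ss_img.generate_state(n) % (2 ** 31)
    cases: list[SyntheticCase] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i:04d}"
        cluster = int(clusters[i])
        mixture = config.cluster_mixtures[cluster - 1]
        diameter_mm = float(np.clip(
            np.exp(rng_cov.normal(math.log(32.0), 0.40)), lo_mm, hi_mm))
        image, mask, habitat_map = generate_tumor_image(
            mixture, diameter_mm, config.archetypes, config.spacing,
            seed=int(img_seeds[i]), blob_size_mm=config.blob_size_mm)
        endpoints = {ep: SurvivalEndpoint(
            float(endpoint_frames[ep]["time"].iloc[i]),
            int(endpoint_frames[ep]["event"].iloc[i])) for ep in ENDPOINTS}
        record = _sample_record(pid, cluster, rng_cov,
                                dmax_cm=diameter_mm / 10.0,
                                endpoints=endpoints)
        cases.append(SyntheticCase(pid, image, mask, habitat_map, record))
        row = {"patient_id": pid, "true_cluster": cluster}
        for ep in ENDPOINTS:
            row[f"lp_{ep}"] = lp[ep][i]
        truth_rows.append(row)
    return cases, pd.DataFrame(truth_rows)


def write_cohort(cases: list[SyntheticCase], truth: pd.DataFrame,
                 outdir: str | Path, config: Optional[CohortConfig] = None,
                 ) -> dict:
    """Write per-patient NIfTI image/mask/true-habitat-map files, the
    clinical and truth CSVs, and a manifest JSON listing paths and seeds."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    manifest = {"patients": [], "n_patients": len(cases)}
    if config is not None:
        manifest["spacing"] = list(config.spacing)
        manifest["seed"] = config.seed
    for case in cases:
        img_p = outdir / "images" / f"{case.patient_id}_image.nii.gz"
        msk_p = outdir / "images" / f"{case.patient_id}_mask.nii.gz"
        map_p = outdir / "images" / f"{case.patient_id}_true_habitats.nii.gz"
        save_case(case.image, case.mask, img_p, msk_p)
        save_label_map(case.true_habitat_map, case.image.spacing, map_p)
        manifest["patients"].append({
            "patient_id": case.patient_id,
            "image": str(img_p.relative_to(outdir)),
            "mask": str(msk_p.relative_to(outdir)),
            "true_habitat_map": str(map_p.relative_to(outdir)),
        })
    clinical_frame([c.record for c in cases]).to_csv(
        outdir / "clinical.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    manifest["clinical"] = "clinical.csv"
    manifest["truth"] = "truth.csv"
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
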