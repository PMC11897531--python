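"""Habitat dictionary, voxel labelling, patient profiles and 2-group clustering.

The habitat dictionary is a single cohort-global K-means codebook over
normalized voxel features, so habitat identities are comparable across
patients.  Each patient is then summarized as a habitat-fraction vector plus
whole-VOI intensity statistics (mean, sample SD, Fisher g1 skewness), and
patients are clustered into two prognostic groups with elbow + silhouette
model selection.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .features import FEATURE_COLUMNS, NormalizationParams

DEFAULT_K_HABITATS = 8
DEFAULT_MAX_VOXELS_PER_PATIENT = 2000
PROFILE_STAT_COLUMNS = ("intensity_mean", "intensity_sd", "intensity_skewness")


@dataclasses.dataclass
class HabitatDictionary:
    """Cohort-global K-means codebook over normalized voxel features."""

    K: int
    centroids: np.ndarray  # (K, d)
    feature_names: tuple[str, ...]
    seed: int
    normalization: Optional[NormalizationParams] = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.centroids.shape[0] != self.K:
            raise ValueError("centroid count != K")
        if len(np.unique(self.centroids, axis=0)) != self.K:
            raise ValueError("centroids must be pairwise distinct")

    def to_json(self, path: str | Path) -> None:
        payload = {"K": self.K, "centroids": self.centroids.tolist(),
                   "feature_names": list(self.feature_names),
                   "seed": self.seed}
        if self.normalization is not None:
            payload["normalization"] = {
                "features": list(self.normalization.features),
                "mean": self.normalization.mean.tolist(),
                "sd": self.normalization.sd.tolist(),
                "dropped": list(self.normalization.dropped),
            }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "HabitatDictionary":
        d = json.loads(Path(path).read_text())
        norm = None
        if "normalization" in d:
            n = d["normalization"]
            norm = NormalizationParams(tuple(n["features"]),
                                       np.asarray(n["mean"]),
                                       np.asarray(n["sd"]),
                                       tuple(n["dropped"]))
        return cls(d["K"], np.asarray(d["centroids"]),
                   tuple(d["feature_names"]), d["seed"], norm)


def subsample_per_patient(table: pd.DataFrame, max_voxels: int,
                          seed: int) -> pd.DataFrame:
    """Uniform seeded subsample of at most ``max_voxels`` rows per patient."""
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in table.groupby("patient_id", sort=True):
        if len(grp) > max_voxels:
            idx = rng.choice(len(grp), size=max_voxels, replace=False)
            grp = grp.iloc[np.sort(idx)]
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def fit_habitat_model(table: pd.DataFrame, K: int = DEFAULT_K_HABITATS,
                      seed: int = 0,
                      max_voxels_per_patient: int = DEFAULT_MAX_VOXELS_PER_PATIENT,
                      feature_names: Optional[Sequence[str]] = None,
                      normalization: Optional[NormalizationParams] = None,
                      n_init: int = 10) -> HabitatDictionary:
    """Fit the habitat codebook on pooled normalized voxel features.

    k-means++ initialization, ``n_init`` restarts, tolerance 1e-6; voxels are
    subsampled per patient first so large tumors cannot dominate the
    dictionary.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if feature_names is None:
        feature_names = (normalization.features if normalization is not None
                         else tuple(f for f in FEATURE_COLUMNS
                                    if f in table.columns))
    sub = subsample_per_patient(table, max_voxels_per_patient, seed)
    X = sub[list(feature_names)].to_numpy(dtype=np.float64)
    if len(X) < K:
        raise ValueError(f"only {len(X)} pooled rows for K={K}")
    if len(np.unique(X, axis=0)) < K:
        raise ValueError(f"fewer than K={K} distinct feature points")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init, tol=1e-6,
                random_state=seed).fit(X)
    return HabitatDictionary(K, km.cluster_centers_, tuple(feature_names),
                             seed, normalization)


def assign_habitats(table: pd.DataFrame, model: HabitatDictionary,
                    chunk: int = 200_000) -> np.ndarray:
    """Label each voxel 1..K by nearest centroid (ties -> lowest label)."""
    X = table[list(model.feature_names)].to_numpy(dtype=np.float64)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.centroids.shape[1]}")
    labels = np.empty(len(X), dtype=np.int32)
    for start in range(0, len(X), chunk):
        d = cdist(X[start:start + chunk], model.centroids)
        labels[start:start + chunk] = np.argmin(d, axis=1) + 1
    return labels


def compute_habitat_profile(labels: np.ndarray, hu: np.ndarray, K: int,
                            patient_id: str = "0") -> dict:
    """Per-patient habitat fractions plus intensity mean/SD/skewness.

    Skewness is Fisher's bias-uncorrected g1 = m3 / m2^(3/2); SD is the
    sample (n-1) convention.
    """
    labels = np.asarray(labels)
    hu = np.asarray(hu, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("empty habitat map")
    counts = np.bincount(labels, minlength=K + 1)[1:K + 1]
    fractions = counts / labels.size
    profile = {"patient_id": patient_id}
    for h in range(K):
        profile[f"habitat_{h + 1}"] = float(fractions[h])
    profile["intensity_mean"] = float(hu.mean())
    profile["intensity_sd"] = float(hu.std(ddof=1)) if hu.size > 1 else 0.0
    profile["intensity_skewness"] = (float(stats.skew(hu, bias=True))
                                     if hu.size > 1 and hu.std() > 0 else 0.0)
    return profile


def habitat_fraction_columns(K: int) -> list[str]:
    return [f"habitat_{h}" for h in range(1, K + 1)]


# ---------------------------------------------------------------------------
# Silhouette and model selection


def silhouette_score(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b-a)/max(a,b).

    Singleton-cluster points contribute 0, and 0/0 (all points coincident)
    is taken as 0.
    """
    X = np.asarray(points, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = cdist(X, X)
    s = np.zeros(len(X))
    members = {c: labels == c for c in uniq}
    for i in range(len(X)):
        own = members[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_num_clusters(points: np.ndarray, k_range: Sequence[int] = range(2, 7),
                        seed: int = 0, n_init: int = 10,
                        ) -> tuple[int, pd.DataFrame]:
    """Scan k: within-cluster SS (elbow) and silhouette; pick argmax silhouette."""
    X = np.asarray(points, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    rows = []
    for k in k_range:
        if k >= len(X):
            break
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6,
                    random_state=seed).fit(X)
        sil = silhouette_score(X, km.labels_)
        rows.append({"k": k, "within_ss": float(km.inertia_),
                     "silhouette": sil})
    diagnostics = pd.DataFrame(rows)
    best = diagnostics.loc[diagnostics["silhouette"].idxmax()]
    return int(best["k"]), diagnostics


# ---------------------------------------------------------------------------
# Patient-level clustering


@dataclasses.dataclass
class ClusterAssignment:
    """Patient -> cluster mapping with model-selection diagnostics."""

    assignments: pd.DataFrame  # columns: patient_id, cluster
    diagnostics: pd.DataFrame  # per-k within_ss and silhouette
    chosen_k: int

    def cluster_of(self, patient_id: str) -> int:
        row = self.assignments.loc[self.assignments["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        return int(row["cluster"].iloc[0])

    @property
    def labels(self) -> np.ndarray:
        return self.assignments["cluster"].to_numpy()


def _patient_feature_matrix(profiles: pd.DataFrame) -> np.ndarray:
    frac_cols = [c for c in profiles.columns if c.startswith("habitat_")]
    cols = frac_cols + list(PROFILE_STAT_COLUMNS)
    X = profiles[cols].to_numpy(dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    return (X[:, keep] - mu[keep]) / sd[keep]


def cluster_patients(profiles: pd.DataFrame, k: int = 2, seed: int = 0,
                     use_pca: bool = True, variance_kept: float = 0.95,
                     event_indicator: Optional[np.ndarray] = None,
                     k_range: Sequence[int] = range(2, 7),
                     n_init: int = 10) -> ClusterAssignment:
    """Cluster patients on z-scored habitat profiles.

    The patient vector is the K habitat fractions concatenated with the
    intensity mean/SD/skewness, z-scored; an optional PCA keeps
    ``variance_kept`` of total variance before K-means.  Cluster labels are
    renumbered so cluster 1 is the worse-prognosis group (higher event rate
    under ``event_indicator``); without an event indicator the ordering falls
    back to the first feature coordinate of the centroids, which is
    deterministic but carries no prognostic meaning.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds {len(profiles)} patients")
    Z = _patient_feature_matrix(profiles)
    if use_pca and Z.shape[1] > 1:
        n_comp = min(len(Z) - 1, Z.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
        Y = pca.fit_transform(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        keep = int(np.searchsorted(cum, variance_kept) + 1)
        Z = Y[:, :keep]
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6,
                random_state=seed).fit(Z)
    raw = km.labels_
    if event_indicator is not None:
        ev = np.asarray(event_indicator, dtype=np.float64)
        rates = [ev[raw == c].mean() for c in range(k)]
        order = np.argsort(rates)[::-1]  # worst prognosis first
    else:
        order = np.argsort(km.cluster_centers_[:, 0])[::-1]
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    clusters = np.array([relabel[int(c)] for c in raw])
    if len(k_range):
        chosen_k, diagnostics = select_num_clusters(Z, k_range=k_range,
                                                    seed=seed, n_init=n_init)
    else:  # diagnostics scan skipped
        chosen_k = k
        diagnostics = pd.DataFrame(columns=["k", "within_ss", "silhouette"])
    assignments = pd.DataFrame({
        "patient_id": profiles["patient_id"].to_numpy(),
        "cluster": clusters,
    })
    return ClusterAssignment(assignments, diagnostics, chosen_k)


def compare_habitat_distribution(assignment: ClusterAssignment,
                                 profiles: pd.DataFrame,
                                 ) -> tuple[pd.DataFrame, tuple[float, int, float]]:
    """Between-cluster habitat comparison.

    Per habitat: Wilcoxon rank-sum of fraction distributions between the two
    clusters.  Global: Pearson chi-squared (no continuity correction) on the
    2 x K contingency table of each patient's dominant habitat.
    """
    merged = profiles.merge(assignment.assignments, on="patient_id")
    clusters = sorted(merged["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need two clusters present")
    frac_cols = [c for c in merged.columns if c.startswith("habitat_")]
    rows = []
    g1 = merged[merged["cluster"] == clusters[0]]
    g2 = merged[merged["cluster"] == clusters[1]]
    for col in frac_cols:
        if len(g1) < 2 or len(g2) < 2:
            import warnings
            warnings.warn("cluster with < 2 patients; rank-sum skipped",
                          stacklevel=2)
            rows.append({"habitat": col, "statistic": np.nan, "p": np.nan})
            continue
        stat, p = stats.ranksums(g1[col], g2[col])
        rows.append({"habitat": col, "statistic": float(stat), "p": float(p)})
    per_habitat = pd.DataFrame(rows)

    dominant = merged[frac_cols].to_numpy().argmax(axis=1)
    table = np.zeros((2, len(frac_cols)))
    for ci, c in enumerate(clusters[:2]):
        sel = merged["cluster"] == c
        table[ci] = np.bincount(dominant[sel], minlength=len(frac_cols))
    # drop habitats never dominant in either cluster (zero expected counts)
    table = table[:, table.sum(axis=0) > 0]
    chi2, dof, p = chi_squared_independence(table)
    return per_habitat, (chi2, dof, p)


def chi_squared_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction."""
    table = np.asarray(table, dtype=np.float64)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    if total == 0 or dof == 0:
        return 0.0, int(dof), 1.0
    expected = rowsum * colsum / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, int(dof), float(stats.chi2.sf(chi2, dof))
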