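# habistrat

CT habitat analysis and prognostic stratification for colorectal liver
metastases (CRLM).

Intratumoral heterogeneity is prognostic: different subregions of a liver
metastasis ("habitats") carry different imaging phenotypes — intensity,
texture, enhancement — and their composition varies between patients.
`habistrat` implements the full analysis that turns a contrast-enhanced CT
volume plus a tumor segmentation mask into a habitat-based prognostic model
and compares it head-to-head against the two standard clinicopathologic
scores:

1. **Voxel habitat dictionary.** Inside each tumor VOI, five features per
   voxel (HU, neighborhood mean, sample SD, 32-bin histogram entropy,
   mask-restricted gradient magnitude) are z-scored cohort-wide and
   clustered with K-means (K = 8 by default) into a single cohort-global
   habitat codebook, so habitat identities are comparable across patients.
2. **Patient clustering.** Each patient is summarized by their habitat
   fraction vector plus whole-VOI intensity mean / SD / skewness; K-means
   (with elbow + silhouette model selection over k = 2..6) splits the cohort
   into two prognostic clusters, cluster 1 being the worse-prognosis group.
3. **Comparator scores.** Tumor Burden Score
   TBS = sqrt(d_max² + n²) with low/medium/high zones at 3 and 9, and a
   Fong-style Clinical Risk Score (0–5 points, high ≥ 3).
4. **Survival comparison.** For overall survival, disease-free survival and
   liver-specific DFS: Kaplan–Meier curves, log-rank tests, Cox PH models,
   and the censoring-corrected model-comparison metrics — Harrell's
   C-index, integrated Brier score (IBS), cumulative/dynamic time-dependent
   AUC at years 1–10, and continuous NRI / IDI — all using
   inverse-probability-of-censoring weights (IPCW) with bootstrap 95%
   intervals.

Because the original imaging cohort requires a large download, the package
ships a first-class synthetic cohort generator (`habistrat.cohort`) that
plants known ground truth: ellipsoidal tumors tiled with intensity-distinct
habitat blobs, two latent patient clusters with different habitat
compositions, and exponential proportional-hazards survival with
cluster-dependent hazard and independent censoring. Every stage of the
pipeline is validated against this ground truth.

## Worked example

```python
from habistrat import CohortConfig, HabitatAnalysis

config = CohortConfig(n_patients=24, tumor_size_range=(10.0, 20.0),
                      spacing=(1.0, 1.0, 1.0), blob_size_mm=3.0, seed=7)
results = HabitatAnalysis.from_synthetic(config,
                                         max_voxels_per_patient=1000).fit()
print(results.summary().to_string(index=False))
```

```
 endpoint   model  c_index     c_index_95ci    ibs         ibs_95ci
       os     crs   0.4141 (0.2484, 0.5704) 0.1991  (0.1526, 0.207)
       os     tbs   0.4868 (0.3601, 0.6014) 0.1935  (0.133, 0.2099)
       os habitat   0.5551 (0.4359, 0.6835) 0.1959 (0.1284, 0.2054)
      dfs     crs   0.6589 (0.5077, 0.8075) 0.1686 (0.1152, 0.1874)
      dfs     tbs   0.5911  (0.457, 0.7143) 0.1619 (0.1073, 0.1983)
      dfs habitat   0.5657 (0.4234, 0.6958) 0.1583 (0.1007, 0.1983)
liver_dfs     crs   0.6014 (0.4253, 0.7614) 0.1884 (0.1353, 0.2084)
liver_dfs     tbs   0.4617  (0.282, 0.6349) 0.1786 (0.1141, 0.2041)
liver_dfs habitat   0.5923 (0.4494, 0.7257) 0.1732 (0.1134, 0.1936)
```

Each row is one comparator model evaluated on one endpoint: `c_index` is
the probability the model ranks the earlier-failing patient of a comparable
pair as higher risk (0.5 = no discrimination), and `ibs` is the
IPCW-corrected mean squared error of the model's predicted survival curves
integrated over follow-up (lower = better calibrated). At this toy size
(n = 24) the intervals are wide; the habitat model still recovers the
planted structure exactly:

```python
results.cluster_sizes()          # {1: 12, 2: 12}
results.assignment.chosen_k      # 2  (elbow + silhouette scan)
results.logrank["liver_dfs"]     # (4.09, 1, 0.0431)  chi2, dof, p
```

and the assignment agrees perfectly with the generator's latent clusters
(adjusted Rand index 1.0 against `results.truth`).

From the shell, the same pipeline runs from a JSON config:

```bash
habistrat simulate --config cfg.json --out cohort_dir   # NIfTI + CSV cohort
habistrat run --config cfg.json                          # full analysis
habistrat metrics --clinical c.csv --assignments a.csv --scores s.csv --out m
```

`habistrat run` writes habitat profiles, cluster assignments, prognostic
scores, the model-comparison table, per-patient habitat label maps (NIfTI),
the Sankey cross-tabulation (CRS category × habitat cluster × TBS zone) and
a metric report JSON; two runs with the same config are byte-identical.

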