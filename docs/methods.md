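# Methods

This note documents the models and procedures implemented in `habistrat`,
the assumptions behind them, the parameters that matter, and what the
synthetic validation does and does not demonstrate.

## Imaging standardization

CRLM cohorts are acquired heterogeneously (slice thickness roughly
2.5–7.5 mm, in-plane pixel spacing ~0.6–1.0 mm). Before feature
extraction every case is resampled to a common grid and intensity window:

- **Target spacing** 1×1×1 mm (trilinear for the image, nearest-neighbour
  for the mask so it stays binary). Output voxel *i* samples the input at
  continuous index *i*·target/source per axis, edge-clamped; the mapping is
  deliberately explicit so a brute-force interpolation oracle can verify it
  voxel by voxel.
- **HU window** (−100, 300), a portal-venous liver range; clipping is
  idempotent. Both defaults are package decisions — published pipelines
  state that standardization happened but rarely the recipe — and both are
  exposed in the config.
- Masks with multiple lesions are pooled: the VOI is simply the set of all
  foreground voxels. Resampling that empties a mask (tumor below
  resolution) is a hard error, not a silent drop.

## Voxel features

Five features per in-mask voxel: raw HU (intensity and, in a single
portal-venous phase, the only available enhancement surrogate), the mean
and sample SD (n−1 convention throughout the package) of the (2r+1)³
neighborhood intersected with the mask, base-2 histogram entropy on a fixed
32-bin grid over the HU window, and a gradient magnitude from central
differences restricted to the mask (one-sided at the boundary, zero where
no in-mask neighbour exists). Neighborhoods are clipped at the mask so
tumor statistics never mix with liver background. Default radius r = 2
voxels at 1 mm spacing. This is a deliberately minimal, interpretable set;
a full IBSI-style radiomics battery is out of scope.

Features are z-scored over the pooled cohort (zero-variance features are
dropped with a warning); the fitted normalization is serializable and
transfers verbatim to held-out patients.

## Habitat dictionary and patient clusters

The habitat codebook is a single cohort-global K-means (k-means++, 10
restarts, tolerance 1e-6, fixed seed) over normalized voxel features, with
per-patient subsampling (default 2 000 voxels) so large tumors cannot
dominate the dictionary. A cohort-global codebook makes habitat label k
mean the same thing in every patient; the alternative (per-patient
clustering plus matching) is not identifiable. Voxels are labelled by
nearest centroid, ties broken toward the lowest label. K defaults to 8 and
is a config, not a constant.

Each patient is summarized as the K-vector of habitat volume fractions plus
the whole-VOI intensity mean, sample SD and Fisher g1 skewness
(bias-uncorrected, m3/m2^{3/2}). Patient clustering z-scores this vector,
optionally projects it linearly onto the components holding 95% of
variance, and runs K-means with k = 2; the elbow curve (within-cluster SS)
and silhouette are scanned over k = 2..6 and the silhouette argmax is
reported. The silhouette uses the standard (b−a)/max(a,b) with singleton
clusters contributing 0 and the 0/0 case defined as 0.

Cluster labels are renumbered so cluster 1 is the worse-prognosis group
when an event indicator is supplied (the pipeline passes OS events);
without one, ordering falls back to the first centroid coordinate — stable
and deterministic, but without prognostic meaning. Renumbering affects
presentation only; every downstream test uses the labels symmetrically.

Between-cluster habitat composition is compared per habitat with Wilcoxon
rank-sum tests on the fraction distributions and globally with a Pearson
chi-squared test (no continuity correction) on the 2×K table of dominant
habitats; columns never dominant in either cluster are removed before the
test so expected counts stay positive.

## Prognostic comparator scores

- **TBS** = √(d_max² + n²), d_max the largest lesion diameter in cm and n
  the lesion count; strictly increasing in both arguments. Zones are
  left-closed at the conventional cut-offs 3 and 9 (low < 3 ≤ medium < 9 ≤
  high), exposed in config because sources vary.
- **CRS** (Fong-style): one point each for node-positive primary,
  disease-free interval < 12 months (synchronous disease counts), more than
  one metastasis, d_max > 5 cm, CEA > 200 ng/mL. Missing CEA scores 0 for
  that criterion and sets a per-patient completeness flag — registry
  practice; nothing is imputed. Low = 0–2, high = 3–5. All other
  covariates are mandatory and raise a named error when absent.

## Survival statistics

Kaplan–Meier uses the product-limit estimator with deaths processed before
censorings at tied times. The log-rank test is the K-sample
observed-minus-expected statistic with the hypergeometric covariance
(dof = groups − 1). Cox models are fitted by lifelines with Efron tie
handling; constant covariates, more covariates than events, and
non-convergence are explicit errors.

The model-comparison metrics treat each comparator as a scalar risk marker
(CRS points, TBS value, habitat cluster indicator with cluster 1 = 1) and,
where survival probabilities are needed (Brier/IBS, NRI/IDI risks), as a
group-stratified Kaplan–Meier predictor: a patient's predicted S(t) is the
KM curve of their own stratum (cluster, CRS category, TBS zone). This
model-as-marker convention is stated in the report metadata.

Censoring is handled by IPCW with Ĝ the reverse Kaplan–Meier (event flags
flipped, risk sets {T ≥ c}, so a subject with an event at exactly c is
still at risk for censoring at c). Ĝ is right-continuous; left limits use
strict inequality. At horizon t: events before t weigh 1/Ĝ(T−), survivors
1/Ĝ(t), subjects censored before t weigh 0; a horizon where Ĝ = 0 raises an
error advising a smaller horizon.

- **Brier score** BS(t) = n⁻¹ Σ wᵢ·(status_t − (1−Ŝᵢ(t)))²; with zero
  censoring it equals the plain mean squared error exactly.
- **IBS** integrates BS(t) by trapezoid over the event-time grid up to
  t_max = min(120 months, last event), anchored at BS(0) = 0, divided by
  t_max.
- **Time-dependent AUC** is the cumulative/dynamic variant (cases: events
  with T ≤ t; controls: T > t), an IPCW-weighted Mann–Whitney probability
  with ties counting ½; evaluated at years 1–10 (12–120 months). The
  incident/dynamic variant is not implemented; the choice is recorded in
  the output metadata.
- **NRI** is the category-free (continuous) flavor at a default horizon of
  60 months — no published risk categories exist for these models — and
  **IDI** the gain in mean risk separation between events and non-events,
  both IPCW-weighted.
- **Bootstrap intervals** are percentile 95% over B = 200 (default)
  seeded resamples of patients, never voxels; a metric failing on more
  than 10% of resamples is an error with the failure tally, not a silent
  NaN. At very small n (≲ 8 patients) degenerate resamples (no comparable
  pairs, empty strata) can exceed this tolerance — the error is the
  intended behavior.

Liver-specific DFS treats non-liver events as censoring; competing-risks
estimators are out of scope.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the statistical
structure the analysis assumes, with full ground truth.

- **Geometry.** One lesion per patient: a random ellipsoid (axis ratios
  0.85–1.15) with a mild smooth boundary perturbation, largest connected
  component kept, so the mask is always a single component. The imaged
  lesion's diameter is the patient's d_max; additional metastases exist
  only as the n_metastases covariate.
- **Habitats.** The interior is tiled by Voronoi cells of seeded points
  with one seed per `blob_size_mm`³ of tumor volume (default 4 mm) — blob
  scale is a tissue property, independent of tumor size. Cells are
  assigned archetype labels by a seeded greedy quota fill against the
  cluster's mixture, which keeps planted blob-volume fractions within a
  few percent of the target (well inside the ±0.10 fidelity band). Eight
  default archetypes have intensity means 20–230 HU spaced 30 HU apart,
  SD 8 HU, and varied texture correlation lengths (Gaussian-smoothed noise
  rescaled to unit variance, so the marginal SD is exact and only the
  correlation length differs).
- **Clusters.** Cluster 1 (worse prognosis) is enriched in habitats 5, 7
  and 8; cluster 2 in habitat 3. Every habitat share differs by ≥ 0.15
  between the mixtures and their L1 overlap Σ min(m₁,m₂) is 0.19, so the
  planted patient-level structure is nearly ideal — the two-cluster
  silhouette of the planted compositions is ≈ 0.96. Cluster allocation is
  exact: round(prevalence·n) patients in cluster 1 (default 96/197) via a
  seeded permutation, so cluster sizes are a configuration echo.
- **Covariates** are sampled to roughly match a real CRLM surgical cohort
  (~58% male, age ≈ 59 ± 13, mean largest lesion ≈ 3.5 cm, ~57% multiple
  metastases, fibrosis Beta(0.5, 2.2), ~15% missing CEA). Exact marginal
  calibration is not a goal and not asserted anywhere.
- **Survival.** Event times are exponential proportional hazards,
  hazard = h₀·exp(lp) with lp = log-HR·1[cluster 1] (defaults: log 2;
  h₀ = 0.010/0.018/0.014 events·month⁻¹ for OS/DFS/liver-DFS). Censoring
  mixes a uniform time on (0, horizon] with an administrative cutoff at
  the horizon (120 months); the mixing weight is solved in closed form
  from the empirical lp distribution so the expected censored fraction
  matches the target (default 0.30), clamping at the administrative floor.
  The censoring mechanism is independent of lp; the censoring *indicator*
  still correlates with lp through the event times, which is why the
  independence test compares stratified reverse-KM curves rather than raw
  correlations.

**What passing tests show — and don't.** Recovery tests demonstrate that
the pipeline's machinery is correct and that, when data contain two
habitat-composition phenotypes as crisp as the generator plants, the
pipeline finds them (ARI ≈ 1, k = 2 selected, all three endpoints separated
by log-rank in ≥ 90% of replicates at the planted HR of 2). They do not
demonstrate that real CRLM cohorts contain such structure: real tumors have
no discrete archetype library, masks carry segmentation error, scanners add
non-stationary noise, and habitat phenotypes correlate with covariates.
One known quantitative gap is intrinsic to dictionary clustering: K-means
centroids do not align one-to-one with the planted archetypes (the blob
boundary continuum absorbs centroids), which compresses between-cluster
differences in the *recovered* fraction space. Patient-cluster recovery is
unaffected, but the recovered-profile silhouette plateaus around 0.75–0.85
even when the planted-composition silhouette is 0.96; the near-ideal
silhouette regime is therefore checked on the planted compositions.

## Numerical and reporting choices

- All randomness flows from named integer seeds (numpy `default_rng` /
  `SeedSequence`); identical configs give byte-identical CSV/JSON outputs.
- K-means convergence tolerance 1e-6 with ≥ 10 restarts; assignment ties
  go to the lowest habitat label; equidistant patient features resolve by
  k-means++ seeding, which is seed-deterministic.
- Sample SD (n−1) everywhere; skewness is bias-uncorrected g1.
- The IBS integration grid is the observed event-time grid, not an
  arbitrary mesh, so the trapezoid nodes sit exactly where BS(t) steps.
- Per-voxel feature tables are written only on demand
  (`write_voxel_tables`): at study scale they reach tens of millions of
  rows, and all result surfaces are recomputable from the stored profiles,
  assignments, scores and dictionary.
- Scaled problem sizes used by the validation suite (tumors 8–16 mm on a
  1 mm grid, 3 mm blobs, 500-voxel dictionary subsampling, bootstrap
  B = 200) were chosen so the full suite and the acceptance script each
  run in minutes on a single CPU while keeping every statistical check at
  its stated power.

## Known limitations

- Single imaging phase; "enhancement" is represented by portal-venous HU
  only. No contrast dynamics, beam hardening or scanner noise spectra are
  simulated.
- No DICOM-SEG reader is bundled; the documented adapter point is the
  NIfTI image/mask pair (any DICOM-SEG → NIfTI converter slots in front of
  `load_case`).
- The habitat C-index uses a binary cluster marker, which bounds its
  discrimination; continuous habitat risk scores are deliberately not
  invented.
- Proportional-hazards diagnostics, time-varying effects and
  competing-risks analysis are out of scope.
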