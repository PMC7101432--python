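# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `petmodnet`, and what the synthetic cohort does and does not emulate.

## Imaging and segmentation

PET volumes are 3D grids with per-axis voxel spacing in mm. SUV calibration
is body-weight based: `SUV = activity[Bq/ml] × weight[g] / dose[Bq]`, with
decay correction assumed upstream. Two delineation strategies are provided,
both restricted to a half-open voxel search box and both using
26-connectivity:

* **Fixed fraction** — threshold at `f × SUVmax` of the box (default
  f = 0.41), keeping the connected component containing the box maximum.
  Ties for the maximum break at the lowest linear (row-major) index; a
  constant box is flagged degenerate and returns the whole box with a
  warning.
* **Fuzzy adaptive** — a seeded EM fit of a 1D Gaussian mixture (2 or 3
  classes) over the box SUVs; tumor voxels are those with posterior
  membership > 0.5 in the highest-mean class (union of the two highest for
  3 classes), keeping the largest component. This is a fuzzy
  mixture segmenter standing in for the published FLAB algorithm, whose
  internals are out of scope here; masks are provenance-tagged
  `fuzzy_adaptive`. Class variances are floored at (1.5% of the box
  intensity range)²: a class narrower than the effective intensity
  resolution (e.g. an exactly constant background in a noise-free phantom)
  is physically meaningless and would drag the decision boundary onto
  itself. Mixture means are initialized spread over the intensity range
  (data quantiles collapse when one class dominates the box); collapsed
  means trigger a jittered restart, at most 5, then an error.

Paired MATV comparisons use the two-sided Wilcoxon signed-rank test (exact
distribution for n ≤ 15 without zero differences); volumes are skewed, so a
rank test is the defensible default where no test is otherwise specified.
Identical mask lists return p = 1 by convention. On heterogeneous synthetic
cohorts the fuzzy masks are supersets of the 41% masks, reproducing the
qualitative under-estimation of fixed-fraction thresholds on irregular,
heterogeneous tumors.

## Radiomic battery

Exactly 28 features in four categories (intensity 5, shape 7,
co-occurrence 7, size-zone 9); names are listed in
`petmodnet.radiomics.FEATURE_NAMES`. Intensities inside the mask are
discretized by fixed bin number: `bin(x) = floor(B (x − min)/(max − min)) + 1`
with the maximum mapped into bin B (default 64); a constant ROI maps to
bin 1 and is flagged. Because FBN normalizes by the ROI range, texture
features are invariant to affine intensity rescaling — and, conversely,
*relative* measures: a near-constant ROI whose only variation is noise or a
smooth gradient sits at maximal relative ruggedness. This caveat matters
when interpreting heterogeneity features on low-contrast ROIs and is why
the generator's lumpiness→inertia check uses an exactly uniform baseline.

* **Co-occurrence**: ordered voxel pairs at the 13 unique displacement
  directions of the 26-neighbourhood (one per ± pair), symmetrized, merged
  into a single matrix and normalized to 1. Features: angular second
  moment, inverse difference moment, homogeneity, dissimilarity, inertia,
  entropy (log₂), correlation. Degenerate conventions: a single-voxel mask
  yields ASM = 1, others 0, correlation 1; zero marginal variance yields
  correlation 1.
* **Size-zone**: zones are 26-connected components of equal-bin voxels;
  `n(i, s)` counts zones of bin i and size s. Zone percentage, small/large
  area emphasis, intensity and size-zone variability, high/low intensity
  (large area) emphasis follow the standard normalized sums.
* **Shape**: V is the voxel-count volume (MATV in ml); A is the surface
  area of a marching-cubes mesh of the 0.5 level set. The binary mask is
  smoothed with a 0.7-voxel Gaussian before meshing: raw binary marching
  cubes overestimates a digitized sphere's area by ~8% (staircase effect),
  while the smoothed mesh reproduces the analytic sphere area to < 1%
  (thin structures that would vanish under smoothing fall back to the raw
  mesh). Sphericity `= π^{1/3}(6V)^{2/3}/A`, compactness v1
  `= V/(√π A^{3/2})`, compactness v2 `= 36πV²/A³` (identically
  sphericity³), spherical disproportion `= 1/sphericity`,
  surface-to-volume ratio `= A/V`. Two features with no published formula
  available to us are defined explicitly: irregularity `:= 1 − sphericity`
  and maximum distance to background `:=` maximum of the interior Euclidean
  distance transform (mm, anisotropic spacing respected).
* **Intensity**: SUVmax, SUVmean, SUV_COV (population SD / mean), MATV,
  TLG = SUVmean × MATV.

No resampling is performed: features are computed on the native grid, with
spacing entering shape/distance features only; texture adjacency is
grid-based. Cohort feature tables are min-max normalized per feature to
[0, 1]; constant features are dropped with a warning since they cannot act
as regulators. A threshold t on this scale is displayed as `100t%` of the
feature's cohort range — which, for skewed features, need not isolate
anywhere near that percentage of patients.

## Differential expression

The paired pipeline is a native implementation of the standard one-color
limma workflow, cross-checked against the R reference in the test suite:

1. **normexp background correction** per array: the net intensity
   x = foreground − background is modeled as S + B with
   S ~ Exp(mean α), B ~ N(μ, σ²), fitted by maximum likelihood
   (Nelder-Mead from method-of-moments starts matching mean, variance and
   skewness; three jittered restarts before failing). The corrected value
   is E[S | X = x] = μ_sx + σ φ(μ_sx/σ)/Φ(μ_sx/σ) with
   μ_sx = x − μ − σ²/α — strictly positive and increasing in x, computed
   via log-space ratios for deep-negative arguments.
2. **log₂**, then **quantile normalization** between arrays (ties receive
   the mean of the target values they would occupy; the transform is
   idempotent).
3. **Replicate averaging** per probe id, preserving first-occurrence order.
4. **Paired moderated t**: per probe, differences d = tumor − normal;
   the empirical-Bayes prior (d₀, s₀²) is estimated by moment matching on
   log s² (digamma/trigamma moments of the scaled-F model, trigamma inverse
   by Newton iteration; d₀ = ∞ when the observed spread of log s² does not
   exceed its expectation under a common variance). The moderated variance
   is (d₀s₀² + df·s²)/(d₀ + df), t is referred to df + d₀ degrees of
   freedom.
5. **Selection**: BH-adjusted p < 0.01 (strict) and |log₂FC| > 1, where the
   fold change is the mean per-patient paired log₂ difference — the natural
   definition for the paired design.

The expression handed to the module-network learner is the per-patient
paired log₂ ratio of retained probes, centered per probe (the module-network
convention for log-ratio data).

A practical caveat encoded in the generator defaults: quantile
normalization assumes most probes are not differentially expressed. The
synthetic cohorts therefore plant ≤ ~10% of probes (mirroring the ~8%
retention rate of real tumor/normal comparisons); planting half the array
visibly distorts null probes.

## Module network

See the README for the model statement. Numerical and algorithmic choices:

* **Score prior**: normal-gamma (μ₀ = 0, λ₀ = 1, α₀ = 1, β₀ = 1) on
  centered log ratios. β₀ sets the prior variance scale; sensitivity
  analysis on planted cohorts showed that a much smaller β₀ (e.g. 0.1)
  under-penalizes module multiplicity — hard EM then stabilizes
  noise-refined sub-modules (ARI ≈ 0.72 on a 3-module cohort fitted with
  K = 6), while β₀ = 1 recovers the planted partition exactly. All four
  hyperparameters are configurable.
* **Initialization**: seeded k-means on probe expression profiles into
  min(K, n_probes) clusters (K defaults to 50; empty modules are allowed
  during fitting and pruned at output).
* **M-step**: greedy tree search; candidate thresholds are midpoints
  between consecutive distinct sorted feature values; a split is accepted
  only on strict score improvement and only if both sides keep at least
  `min_leaf` patients (default 4, the smallest subgroup the model is meant
  to produce); one further split per side at depth 2. The newly learned
  tree replaces the old one only if it scores higher on the current
  members.
* **E-step**: probes are visited sequentially; each moves to the module
  maximizing its leave-that-probe-out posterior-predictive likelihood
  (leaf-wise normal-gamma predictive with the probe's own values removed
  from the module statistics). Exact ties break to the lowest module
  index. Sequential moves with fixed trees strictly increase the total
  score.
* **Merge moves**: after each E-step, any pair of modules is merged when
  pooling their probes under the better of their trees (or a freshly
  learned tree on the pooled members) strictly increases the total score.
  Pooling genuinely same-regime modules always gains (shared parameters
  explain both); genuinely distinct modules never merge. Without this,
  K larger than the true module count leaves duplicated modules from the
  k-means initialization.
* **Monotonicity** of the total Bayesian score across iterations is
  asserted at run time (tolerance 10⁻⁶ relative); the loop stops when an
  iteration changes nothing, or at `max_iter` = 30.
* The fitted model is invariant to patient order, and identical seeds give
  byte-identical serialized models.

Regulator features are *not* added to the expression matrix, so modules
describing correlations among the image features themselves cannot arise —
a deliberate scope decision.

## Pathways

A local `PathwayDB` = GMT gene sets + a two-level hierarchy mapping each
pathway to exactly one top-level pathway (the synthetic generator ships 24
top levels). Module annotation: probe→gene via a TSV annotation table
(uppercase-normalized, replicates deduplicated); over-representation by the
hypergeometric upper tail against a universe defaulting to all annotated
array genes with a pathway mapping; BH across pathways; "altered" means
p_BH < 0.05 and overlap ≥ 2 (both configurable — no canonical criterion
exists, this is standard over-representation practice). Roll-up: each
altered pathway counts once toward its top-level parent; percentages sum to
100; modules are flagged at > 50% and ≥ 30% dominance and as reportable
when more than 10 pathways are altered.

## Synthetic cohort

The generator emulates the study conditions the pipeline is designed for —
45 patients by default, one primary tumor each:

* **Phantoms**: radially perturbed ellipsoids (smooth random radial field,
  amplitude in mm) on a 48³ grid of 4 mm voxels; uniform tumor uptake plus
  0-6 Gaussian lumps of ±(0.5-1)×amplitude SUV; Gaussian PSF blur of 5 mm
  FWHM emulating the reconstruction post-filter; i.i.d. Gaussian noise
  truncated at 0 (post-reconstruction PET noise is approximately Gaussian;
  Poisson counting noise lives upstream of reconstruction and is not
  modeled). Cohort ranges (radius 12-28 mm, eccentricity 0.7-1.3, base
  uptake 5-12 SUV) span more than a 3-fold MATV range and homogeneous to
  strongly heterogeneous uptake. The ground-truth mask is the pre-blur
  support.
* **Expression**: probe baselines ~ N(8, 1) log₂ units (typical microarray
  scale); tumor log₂ signal = baseline + planted leaf offset + N(0,
  probe_sd²) with probe_sd = 0.25; normal = baseline + noise. Default leaf
  offsets (3, 1): every planted probe clears the fold-change filter
  (mean paired difference ≈ 2) while leaving a 2-unit between-leaf contrast
  for the module learner. Raw foreground = 2^signal + additive
  N(bg_mean, bg_sd²) background with an independently drawn background
  channel, so normexp has real work to do; foregrounds are strictly
  positive whenever bg_mean > 5·bg_sd. Replicate probes are duplicated
  with independent noise.
* **Annotation/pathways**: each planted module draws 80% of its genes from
  the pathways of one top-level family, the rest (and all null probes)
  uniformly from the database.

What it does **not** emulate — and hence what green tests do *not*
establish about clinical data: scanner physics (sinograms, attenuation,
partial-volume structure beyond a stationary Gaussian PSF), anatomically
realistic tumor shapes, probe-specific hybridization biases, batch and
hospital effects, correlated gene-gene expression beyond the planted module
structure, and any real biological pathway content. The planted generative
model is exactly the model class the learner fits, which makes parameter
recovery a well-posed check of the implementation, not evidence that real
tumors follow the model.

## Desk-scale problem sizes

The default validation sizes are chosen as the package's own desk-scale
conditions: texture oracles on 100 random 4³ grids; quadrature checks on 50
random leaf inputs; module recovery on 45 patients × 300 probes (K = 6);
null calibration on 5000 probes × 10 patients; and 20 end-to-end repeats of
a 12-patient, 2-module study (30 probes per module + 540 null probes, 32³
phantom grids). The full test suite and the acceptance script each complete
in a few minutes on a single CPU.

## Known limitations

* The fuzzy segmenter is not FLAB; only mask-level behavior (adaptive
  boundaries, superset of 41% masks on heterogeneous tumors) is emulated.
* Hard (winner-take-all) EM: no soft module memberships, and recovery can
  leave a residual split module on unlucky seeds (ARI ≈ 0.87 instead of
  1.0) when per-probe noise means straddle two stable configurations.
* The moderated-t prior estimation uses moment matching on log s²; the
  exact small-sample REML refinements of the reference implementation are
  out of scope (agreement is checked at the pipeline level, not
  coefficient-for-coefficient).
* Texture adjacency ignores anisotropic spacing (grid neighbors are
  neighbors); this matches the no-interpolation policy but means texture
  features are not comparable across grids with different anisotropy.
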