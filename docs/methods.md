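# Methods

`vmi-radstab` studies how radiomic features behave across virtual
monoenergetic images (VMI) from dual-energy CT: which features survive a
test–retest repeat, which survive a change of energy, dose or scanner, and
what feature screening does to a downstream classifier. Because no scan data
ships with the package, a synthetic phantom generator supplies the study
material; everything downstream of the generator — preprocessing, feature
definitions, agreement statistics, cross-validation — is the generic
machinery a real study would use.

## The synthetic phantom

The scene is 16 ellipsoids, four per class, on a 4×4 lattice inside a 64 mm
cube sampled at 1 mm isotropic spacing. The four classes are produce-like
archetypes spanning the fat-to-soft-tissue attenuation range (class means at
the 75 keV reference: −179, −29, −5 and +45 HU) with distinct shapes
(near-sphere, oblate bulb, large sphere, prolate berry) and distinct
stationary Gaussian textures (correlation lengths 1.2–4.5 mm, amplitudes
18–40 HU). Within-class individuality is a seeded ±4 % jitter of the class
radii plus an object-specific texture realization. These defaults are the
package's study conditions: four clearly separated classes, the regime in
which the classification analysis is meant to saturate.

**Energy.** Each object carries an energy-sensitive component
(`iodine_frac`); its mean attenuation at energy *E* is
`base_hu + iodine_frac · k(E)` with a tabulated, strictly decreasing
contrast law `k` anchored at `k(75 keV) = 100` HU. This is a one-parameter
contrast model, not spectral physics: the analysis only needs monotone
energy-dependent contrast. The per-class `iodine_frac` values are free
design parameters (only 120 kV means are known for real produce).

**Noise.** The voxel noise standard deviation is
`σ = σ0(scanner) · g(E) · sqrt(15 mGy / dose)` with `σ0 = 8` HU for the
dual-source mode (DSDE) and `12` HU for the split-filter mode (SFDE), and
`g` minimised at 75 keV (`g(40) = 2.0 … g(190) = 1.35`). The square-root
dose law is exact by construction. SFDE noise is additionally smoothed
(0.6 voxel Gaussian) to emulate its coarser noise grain. Because VMIs at
different energies are synthesized from one acquisition, all energies of a
given (scanner, dose, repeat) share two base noise fields, mixed by an
energy-dependent rotation; the noise correlation between two energies is
the cosine of their angle difference and decays monotonically with the
energy gap. This is what gives cross-energy reproducibility its gap
structure.

**Test–retest.** The retest scan applies one seeded rigid repositioning of
the whole scene (≤ 2 mm in-plane, ≤ 1 mm axial translation, ≤ 3° rotation
about z) and fresh noise. Texture is a stable property of object identity:
the canonical texture block is resampled at the transformed coordinates, so
an object keeps its texture across conditions and repeats. Masks are exact
ellipsoid membership of voxel centres — segmentation is out of scope, so
shape features see geometry only, never noise.

**What the generator does not emulate.** Beam hardening, scatter, partial
volume at interfaces, reconstruction-kernel correlations beyond the two
knobs above, and lesion-like morphology. Passing tests therefore demonstrate
the correctness and internal consistency of the statistics and the pipeline,
not clinical-scale effect sizes. Two scale differences against real scans
are worth knowing: voxel-count agreement between repeats is aliasing-limited
(4–6 % at 5 mm radii on a 1 mm grid; the 2 % contract is asserted on a
0.5 mm fixture where radii are ~11 voxels), and the phantom's
noise-to-biological-variance ratio is higher than in real produce scans, so
repeatable-feature percentages land near 40–50 % rather than 74–86 %,
with the qualitative ordering (dual-source at high dose best) preserved.

## The controlled feature-table generator

For statistics-level checks a second generator skips images entirely. Per
feature, a latent per-object value `class_effect · class_code + N(0, τ²)`
is observed twice with independent noise `N(0, σ²)`, where `τ² + σ² = 1`
and `τ²/(τ² + σ²) = target_ccc`. The population concordance of each feature
then equals its target, enabling parameter-recovery tests (the estimator
converges to the target as the number of objects grows). A nonzero class
effect adds separation on top of the unit latent variance (raising realized
concordance above the target — the formula is taken literally). The
energy-graded variant adds a per-feature Gaussian random walk across
ordered energy levels, so concordance between levels decays monotonically
with their separation.

## Preprocessing and the feature catalogue

The chain is resample → rescale → discretize.

* **Resampling** to 1 mm isotropic uses separable degree-5 Lagrange
  polynomial interpolation with a 6-point stencil clamped inside the
  domain — this reproduces polynomial fields up to degree 5 exactly,
  including at boundaries (the implementation is hand-written because
  B-spline interpolators are not Lagrange polynomials and their boundary
  handling breaks exact ramp reproduction). Masks use nearest neighbour.
* **Rescaling** maps in-mask voxels to `500 · (x − μ)/σ` (population
  moments). This is the standard reading of "relative intensity rescaling
  with a scale of 500"; it deliberately destroys location/scale information,
  so features like the in-mask mean and RMS become constants plus noise and
  correctly fail every stability screen. It is exposed as a switch
  (`apply_rescale`) for workflows that discretize raw HU.
* **Discretization** uses the fixed-bin-size rule anchored at the in-mask
  minimum: bin index `floor(x/w) − floor(min/w) + 1`, default width 25.

The catalogue is 51 features across seven families: 16 first-order, 6 shape,
8 GLCM, 6 GLRLM, 5 GLSZM, 5 NGTDM, 5 GLDM. Texture matrices use 13 unique
unit directions (GLCM symmetrized and normalized per direction; GLRLM runs
broken by the mask), 26-connected zones (GLSZM) and 26-neighbourhoods
(NGTDM, GLDM with dependence tolerance α = 0). Per-direction features are
averaged, not matrix-merged. Numerical conventions: surface area counts
exposed voxel faces (which overestimates smooth surfaces by ≈ 3/2, so a
rasterized ball's sphericity plateaus near 2/3 — the feature remains a valid
*relative* compactness measure); the maximum 3D diameter uses voxel corner
vertices via the convex hull; NGTDM coarseness is capped at 1e6 and all
denominators are guarded by ε = 1e-12; degenerate inputs (single in-mask
voxel, single gray level) return fixed documented values (GLCM: energy 1,
entropy 0, contrast 0, correlation 1) so tables stay dense. Every
matrix-family implementation is cross-checked against independent
brute-force enumerators to 1e-10 in the test suite.

## Stability statistics

Agreement between paired measurement sets uses Lin's concordance
correlation coefficient with population moments,
`CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` (the bias-corrected sample
variant differs by O(1/n) and is not used), and the normalized dynamic
range `DR = 1 − mean|xᵢ − yᵢ| / (max(x∪y) − min(x∪y))`. A feature is
*repeatable* when CCC ≥ 0.9 **and** DR ≥ 0.9 (test–retest), *reproducible*
across two conditions when CCC ≥ 0.9 alone. Degenerate pairs (zero variance
and zero mean gap) yield NaN and count as failing. Group percentages are
compared with one-way ANOVA plus Tukey HSD (scipy); identical groups return
the documented early result F = 0, p = 1.

## Classification evaluation

With 16 objects, a held-out test *set* is wasteful; instead every unordered
pair of objects is held out once (tournament-leave-pair-out, `C(16,2) = 120`
splits). Models are fit per fold inside a pipeline of median imputation,
standardization and the classifier, all fit on the training fold only. For
each class, the pair member with the higher predicted probability wins the
tournament (ties half each, preserving the exact conservation law: wins per
class sum to n(n−1)/2). Win counts are rank scores for one-vs-rest
Mann–Whitney AUCs (ties ½), averaged over classes. Pooled out-of-sample
probabilities give the multiclass Brier score
`BS = mean Σ_k (p_k − y_k)²` and `R² = 1 − BS/BSmax`, where BSmax is the
score of the non-informative model that always predicts the training class
frequencies.

Two learner families sit behind a common contract: multinomial logistic
regression with elastic-net penalty (scikit-learn saga; defaults C = 10,
l1_ratio = 0.7 — light ridge with sparse pruning of noise features, chosen
as the package default for the no-search path) and random forests.
Hyperparameter search draws seeded random configurations (elastic net:
C log-uniform over 1e-3…1e3, mixing uniform; forest: 100–1000 trees, depth,
feature fraction) and corrects the winner's optimism by bootstrap bias
correction: objects are resampled with replacement; per replicate the
configuration minimizing the in-bag Brier score (predictions weighted by
object multiplicity) is scored on the out-of-bag objects; the corrected
metric is the mean over replicates (default B = 500; replicates with an
empty out-of-bag set are redrawn). Out-of-bag AUC uses the winning
configuration's win scores restricted to out-of-bag objects.

## Pipeline, seeding, determinism

One YAML configuration and one master seed drive the full run
(simulate → extract → stability → classify → report). Stage seeds derive
from the master seed by fixed offsets; the scene seed fixes geometry and
per-object texture seeds; each (scanner, dose, repeat) has its own noise
seeds. Re-running a configuration reproduces all tabular outputs
bit-identically — feature CSVs are written with 17 significant digits and
parsed with round-trip precision to make that literal. A manifest records
the configuration hash and output inventory; the expensive extraction stage
is skipped on re-runs when its outputs exist under the same hash (the cheap
downstream stages are recomputed).

## Problem sizes used by the shipped checks

The default phantom (16 objects, 64³ voxels) is extracted at 5 energies ×
2 repeats in ≈ 40 s; the full scanner × dose × energy grid in ≈ 3 min.
Parameter-recovery checks use 1000 objects; the bootstrap-null check uses
16 objects, 30 features, 20 configurations and 500 bootstrap replicates,
averaged over several independent dataset replicates because a single
16-object null dataset carries ~0.15 of AUC sampling spread that bias
correction rightly leaves in place.
These sizes were chosen so a complete verification run stays in the
minutes range on one CPU.

## Known limitations

* The phantom's texture classes are far better separated than clinical
  lesion classes; classification results here say "the machinery is
  correct", not "radiomics classifies lesions".
* The 51-feature catalogue omits filtered-image (wavelet, Laplacian of
  Gaussian) families, so the share of intrinsically noise-like features is
  higher than in a 1218-feature catalogue; with the full catalogue the
  classifier occasionally flips a single tournament that feature screening
  would have avoided.
* Confidence intervals for the evaluation metrics are not implemented; the
  bootstrap machinery reports point estimates and the naive/corrected gap.
* Sphericity and maximum diameter are aliasing-limited on coarse grids (see
  above); volume, surface area and the principal-axis ratios are the
  reliable shape features at 1 mm.
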