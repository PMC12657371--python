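# Methods

This note documents the models implemented in glymphkit, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducing results.

## Diffusion tensor fitting and the ALPS index

Per voxel the mono-exponential model ln(S/S₀) = −b·gᵀDg is solved over the
b > 0 volumes by linear least squares, with S₀ the mean of all b = 0
volumes (averaging the b0s reduces noise when several are acquired). The
default estimator is weighted least squares with weights equal to the
squared predicted signal from an initial ordinary pass — the standard
correction for the heteroscedasticity introduced by the log transform; an
unweighted (`ols`) fit is available. Voxels with non-positive S₀ or signal
are flagged, given a zero tensor, and excluded from ROI statistics.
Fitting requires at least six independent gradient directions (the design
matrix must have rank 6).

Eigenvalues are sorted descending; FA uses the standard eigenvalue formula
with negative eigenvalues clamped to zero *for FA and color-FA only* — the
raw fitted tensor, including any negative diagonal entries, is what enters
the ALPS ratio, so the clamp cannot bias the index. Color-FA is
|principal eigenvector|·FA per channel.

ROIs are spheres specified in world (RAS mm) coordinates; a voxel belongs
to the ROI when its center lies within diameter/2 of the ROI center
(default diameter 5 mm). Diagonal diffusivities are averaged arithmetically
over unflagged ROI voxels **in the native image axes** — no reorientation
into local fiber frames — which presumes an axial acquisition aligned with
the scanner frame, the setting in which the ALPS x/y/z decomposition is
defined. ALPS = mean(Dxx_proj, Dxx_assoc)/mean(Dyy_proj, Dzz_assoc); a
non-positive denominator raises with a diagnostic rather than returning an
unusable value. ROI placement is taken from configuration (in clinical use
it is a manual, rater-dependent step; coordinates are the reproducible
interface, and `stats.icc_absolute_agreement` is provided for quantifying
rater agreement on repeated placements).

### DWI phantoms

Phantoms are block layouts of regions with known tensors; the signal
follows the forward model exactly, so the noiseless fit must invert it to
numerical precision (observed ≲ 10⁻¹⁸ mm²/s; the test bound is 10⁻⁹). Noise
is Rician — magnitude MR statistics — with σ = S₀/SNR per channel.
Diffusivities default to canonical single-fiber white-matter values
λ∥ = 1.7·10⁻³, λ⊥ = 0.3·10⁻³ mm²/s, with an isotropic background at
0.8·10⁻³ mm²/s. The gradient scheme is 64 near-uniform directions
(deterministic Fibonacci sphere) at b = 1000 s/mm² plus five b = 0 volumes.

In the ALPS demonstration phantom both fiber blocks carry their dominant
eigenvalue **along x**, the perivascular direction, which runs
perpendicular to the projection (z) and association (y) fiber systems.
This is a deliberate design choice: it makes the end-to-end pipeline
return exactly λ∥/λ⊥ = 5.667, an arithmetic oracle that pins down every
step (fit → ROI → extraction → ratio). Orienting the dominant axis along
the fiber directions instead would place identical perpendicular
diffusivities in all four slots and force ALPS = 1 — indistinguishable
from the isotropic null phantom, and useless as an oracle. The generator
itself accepts arbitrary eigenvalues and axes per region.

## PVS quantification

Processing order is filter-then-divide: T1w and T2w are each denoised by
non-local means (patch radius 1, search radius 3; smoothing strength
h = 0.8·σ̂ with σ̂ a wavelet-domain MAD noise estimate, the conventional NLM
setting; h = 0 is an exact identity), then EPC = T1w/max(T2w, ε) with
voxels below the ε floor masked out. Inputs are assumed bias-corrected and
co-registered; the phantoms are generated bias-free, so no non-uniformity
correction stage exists here.

Frangi vesselness per scale σ: the Hessian of the σ-smoothed image is
scale-normalized by σ² (γ = 2), eigenvalues are sorted by magnitude
|λ₁| ≤ |λ₂| ≤ |λ₃|, and the response is
(1−exp(−R_A²/2α²))·exp(−R_B²/2β²)·(1−exp(−S²/2c²)) with R_A = |λ₂|/|λ₃|,
R_B = |λ₁|/√|λ₂λ₃|, S the Frobenius norm; the response is gated to zero
where the eigenvalue signs contradict the polarity (dark tubes — PVS on
EPC — require λ₂, λ₃ > 0). The final map is the maximum over scales, hence
monotone non-decreasing in added scales and bounded in [0, 1].

Defaults: α = β = 0.5 (the canonical discrimination weights), c adaptive
at half the maximum Frobenius Hessian norm per scale (makes the
structureness term contrast-invariant; a flat image yields zero response),
polarity dark. Scales {0.4, 0.8, 1.2, 1.6} mm, segmentation threshold 0.1,
minimum cluster 3 voxels (26-connectivity, which preserves thin oblique
tubes): these were calibrated once on the standard tube phantom — radii
1–2 mm, 30% T1/T2 contrast, noise SD 5% of background — to the detection
targets (≥ 90% of true tube voxels recovered under noise; Dice ≥ 0.7
noiseless, observed 0.72 with sensitivity 0.91–0.96 across noise seeds).
Scales extending to 2 mm blur a halo around 1-mm tubes and drop the
noiseless Dice to ~0.5, which is why the set is shifted slightly below
the tube radii. All of these are exposed in `FrangiParams` and the
segmentation arguments.

Volume fractions: VF = 100·(PVS voxels∧region)·voxel-volume / GM+WM
volume. The denominator is the **whole-brain** GM+WM volume for every
region (so regional VFs are additive and the basal-ganglia aggregate —
caudate ∪ putamen ∪ pallidum ∪ amygdala — equals the sum of its parts over
the common denominator); a region-local denominator is available via
`denominator="region"` since the normalization convention is a genuine
modeling choice. Left/right/total rows are reported per structure.

### Structural phantoms

Tubes are straight cylinders voxelized by the center-of-voxel membership
rule — chosen because it is the simplest rule an independent brute-force
point-in-cylinder oracle can reproduce exactly. Intensities: uniform
background, T1 lowered and T2 raised by a fractional contrast inside
tubes, additive Gaussian noise (appropriate for structural images at
typical SNR, unlike the Rician DWI case). The atlas is a set of disjoint
box nuclei mirrored across the midline inside an ellipsoidal tissue mask —
topologically faithful (two hemispheres, labeled subcortical structures
inside a GM+WM mask) but not anatomically shaped.

## Cohort generator

Three groups (HC / CSVD-NCI / CSVD-MCI, default 40/52/68 — study-scale
counts) with demographics, vascular risk factors, ordinal imaging grades,
raw cognitive tests, the ALPS index and regional PVS VFs. The mediation
chain X = putamen PVS VF → M = ALPS → Y = MoCA is planted linearly with
defaults a = −0.08 ALPS units per %VF, b = 8 MoCA points per ALPS unit,
c′ = −1.5 (residual SDs 0.11 and 2.5) — signs follow the hypothesized
physiology (more PVS burden → lower ALPS → worse cognition) and magnitudes
put group means and SDs at clinically plausible values (ALPS ≈ 1.2–1.4,
MoCA ≈ 20–26). Group intercepts are solved so the expected group means of
M and Y hit the targets of the effect model, letting planted group effects
and planted mediation coexist. Setting `effect_model=None` /
`covariates=None` reduces the generator to the bare structural model
(standard-normal exposure, zero intercepts), which is what the
parameter-recovery and coverage simulations use. Generation is
bit-reproducible from a single seeded generator with a fixed draw order.

What the generator does **not** emulate: measurement error linking the
imaging phantoms to the cohort columns (the phantom pipeline and the
cohort statistics are validated separately), non-linear dose-response,
item-level cognitive scores, missing data, or selection effects. Passing
tests therefore demonstrate correctness of the estimators under the
generating model, not robustness to real-data pathologies.

## Statistical layer

- **z-scores:** (score − HC mean)/HC SD with the sample SD (n−1; the
  conventional reference-group standardization). Time-based domains
  (executive = TMT-B, processing speed = TMT-A) are multiplied by −1
  after standardization. HC mean 0 / SD 1 is a construction identity and
  is asserted to 10⁻¹².
- **Group comparisons:** Shapiro–Wilk per group and Levene (median-
  centered) at α = 0.05 choose ANOVA vs Kruskal–Wallis; categorical
  variables use Pearson chi-square without continuity correction (this is
  the convention that reproduces standard two-decimal table p-values from
  raw counts). Pairwise follow-ups match the omnibus branch and are
  Bonferroni-multiplied, capped at 1.
- **Partial correlation:** residualized Pearson on [1, covariates]
  (equivalent to the inverse-correlation-matrix definition, which serves
  as the independent oracle), p from t with df = n−2−k. Binary covariates
  are coded 0/1, sex male = 1.
- **FDR:** Benjamini–Hochberg step-up within user-declared families
  (e.g. ALPS~PVS and ALPS~cognition as separate families); family
  membership is configuration, not inference.
- **ICC:** single-measure absolute-agreement ICC(A,1) from two-way mean
  squares with the standard F-based 95% CI; missing cells are rejected
  rather than imputed.
- **Mediation:** OLS paths with identical covariates in both models, so
  c = c′ + a·b holds exactly (asserted to 10⁻¹⁰); percentile bootstrap
  (default 5000 replicates) over subjects with rank-deficient replicates
  redrawn and counted. The percentile CI was chosen over BCa as the
  simplest defensible interval; the mediated share 100·(a·b)/c is reported
  as NaN under inconsistent mediation (indirect and total of opposite
  sign), where the ratio has no interpretation. Standardized paths are
  reported alongside the raw ones since the indirect effect's magnitude
  depends on the exposure's scale (fraction vs percent changes it by 100).

## Problem sizes and determinism

Default analysis sizes: 32³ DWI phantom grids (2-mm voxels, 69 volumes),
48×56×48 structural grids (1-mm voxels, 6 tubes), 160-subject cohorts,
5000 bootstrap replicates. The simulation-based checks use n = 2000
cohorts for parameter recovery and 200 simulated datasets × 1000 bootstrap
replicates (n = 300 each) for null-coverage of the indirect-effect CI —
sizes at which the Monte-Carlo error is comfortably below the tested
tolerances. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; pipeline outputs embed the seed and a config
hash, and repeated runs are byte-identical.

## Known limitations

- The atlas and phantoms are geometric, not anatomical; registration,
  bias-field correction, brain extraction and tissue segmentation are out
  of scope (masks are inputs).
- ALPS diffusivities are read in image axes; oblique acquisitions would
  require tensor reorientation that is deliberately not implemented.
- Single-mediator linear mediation only; no moderated or multiple-mediator
  models, no missing-data handling.
- Cortical/white-matter PVS are not quantified — only the labeled
  subcortical nuclei.
- The Frangi defaults are calibrated to the standard phantom's tube
  calibers and contrast; substantially different PVS geometry or contrast
  warrants re-tuning via `FrangiParams`.
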