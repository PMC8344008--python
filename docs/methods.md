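# Methods

## Segmentation model

A scan is a 3-D SUV grid with voxel spacing in mm; world coordinates are
`index × spacing` (voxel-center, 0-based, no oblique affine). SUV values
are assumed decay- and body-weight-corrected upstream — SUV conversion is
out of scope.

The adaptive threshold is `(4.3 / liver_mean) × (liver_mean + liver_sd)`.
With a noiseless liver it equals the reference constant 4.3; it grows
linearly in the liver coefficient of variation, which protects against
calling liver-level noise "lesion". The liver reference region is an
explicit input: either a whole-organ mask or a spherical VOI placed with
`sphere_roi` (the delineation convention is not standardized in the field,
so both are supported). Liver SUVsd defaults to the population (ddof = 0)
convention, configurable via `sd_ddof`.

Boundary conventions are fixed and asymmetric by design: *detection* keeps
voxels strictly above the threshold ("greater than"), *refinement* keeps
voxels at or above 50% of the local SUVmax (the isocontour is inclusive).
Both use 26-connectivity, the standard for PET hot-spot labeling; the
brute-force oracles in the tests share the same declared convention, so
equivalence checks are meaningful.

The 50% refinement takes the connected component of
`{SUV ≥ 0.5 × local SUVmax}` containing the focus' hottest voxel. It may
extend beyond the initial supra-threshold focus (a deliberate choice: the
isocontour, not the detection threshold, defines the lesion boundary).
Two nearby foci whose isocontours merge yield identical or overlapping
voxel sets; identical sets collapse, overlapping sets merge by union, so a
single physical lesion is never counted twice in PSMA-TV.

Organ exclusion removes a focus when more than `overlap_frac` (default 0.5)
of its voxels lie inside any one masked organ — not any-overlap, so
metastases abutting an organ survive. Reviewer adjustments are explicit
lists: `exclude_foci` coordinates drop their containing focus; an
`include_regions` seed re-inserts a focus even inside an organ mask (the
liver-metastasis path). A forced seed above the threshold brings its whole
supra-threshold component; below it, the singleton seed lets the 50% rule
grow the lesion.

Degenerate inputs: an empty liver mask, a non-positive liver mean, a seed
outside the grid, and non-positive spacing are all rejected with typed
errors rather than propagating NaNs.

## Burden metrics and response

Per lesion: volume (voxel count × voxel volume / 1000, ml), SUVmax, SUVmean
and TLQ = volume / SUVmean. Per scan: PSMA-TV and TLQ are sums; meanSUVmax
is the *unweighted* mean over lesions (not volume-weighted — it proxies
average expression per metastasis). An empty scan has zero burden and a
missing meanSUVmax.

Classifications use strict inequalities — decline > 30% (volumetric),
decline > 50% (biochemical, against the best on-treatment PSA), meanSUVmax
> 14.3 for high expression — so a value exactly on a boundary is a
non-responder / low expression. The responder comparison is evaluated in
the rearranged form `100·(TV_b − TV_i) > 30·TV_b`, which is exact for
representable inputs; the naive percent form misclassifies exact
boundaries through float rounding. A vanished interim volume is a 100%
decline with the ratio stored as missing; a zero baseline leaves response
undefined (missing). Every patient is exactly one of
responder / non-responder / missing.

## Survival analysis

All continuous covariates enter Cox regression and Martingale analysis
natural-log transformed; volumetric response enters as log(TV_baseline /
TV_interim). Cox fits use lifelines with Efron tie handling; missing
covariates are handled complete-case per model with the used n reported.
A constant covariate or < 2 events raises a degenerate-model error; inside
the full analysis plan such sub-models are recorded as degenerate rather
than aborting the run.

The standardized two-sample log-rank statistic uses the hypergeometric
variance. Without tied event times it equals the Cox score test at β = 0;
the suite asserts this identity at 1e-6.

Martingale residuals are hand-computed as `event_i − r_i · H₀(t_i)` with
the Breslow baseline `H₀(t) = Σ_{s ≤ t} d_s / Σ_{j at risk} r_j`. With this
construction the residuals sum to zero *identically* for any risk score —
including coefficients from an Efron-ties fit — which is the zero-sum
diagnostic the tests assert at 1e-8. (Efron-baseline residuals would not
satisfy it exactly; that is why the baseline is Breslow here.)

Cutoff finding (maximally selected rank statistics) scans midpoints between
consecutive distinct covariate values whose induced groups each hold at
least `min_prop` (default 0.1) of patients, and returns the cutoff with the
largest |standardized log-rank|, smallest cutoff on ties. The point
estimate is primary (in the intended use the cutoffs serve visualization);
when a significance level is wanted, a permutation null of the maximal
statistic (default 10 000 permutations) provides the multiple-cutoff
adjustment — a direct Monte-Carlo analogue of the analytic improved-Bonferroni
approximations.

Median splits use the standard midpoint convention with ties to the low
group; an all-equal covariate is a degenerate grouping error. Rank
statistics: Spearman ρ with its default test; Wilcoxon rank-sum with the
exact distribution when the smaller group has ≤ 10 patients, normal
approximation otherwise.

## Phantom generator

The phantom is a uniform background with ellipsoidal organs (liver, spleen,
kidneys; per-voxel Gaussian uptake around the organ mean) and spherical
lesions at constant peak SUV; organ and lesion supports *replace* the
background so the configured means are exact. Lesion/organ and organ/organ
overlaps are rejected — truth masks must be unambiguous. After
rasterization the image is blurred by an isotropic Gaussian PSF of stated
FWHM and degraded with additive Gaussian noise clipped at 0 (SUV-domain
simplicity; Poisson-scaled noise is deliberately not modeled). Truth masks
are the pre-blur supports; truth volume is the voxel-center-in-sphere count
times voxel volume.

The default torso phantom is 64×64×96 voxels at 2 mm (a compact stand-in
for a vertex-to-thigh acquisition), liver SUV 5.0 ± 0.5 (threshold ≈ 4.7),
kidneys SUV 12, spleen 2.5, lesion radii 7–13 mm and peaks 10–25 — chosen
to straddle the clinical scale the cohort simulator targets, since no
lesion-size or uptake distributions are standardized; these are assumptions,
not measurements.

What the phantom does *not* emulate: scatter/attenuation artifacts,
respiratory motion, anisotropic PSF, bladder/gut uptake, heterogeneous
lesion texture. Passing recovery tests therefore demonstrate correctness of
the segmentation logic under controlled blur and noise, not clinical
accuracy on real acquisitions.

## Cohort simulator

Per patient: baseline PSMA-TV is log-normal with median 138 ml and sigma
solved from an IQR of 230 ml (`σ = asinh(IQR/2m)/z₀.₇₅ ≈ 1.13`). The
interim/baseline decline factor is log-normal (`μ = −0.30, σ = 0.45`,
giving ~45% of patients a > 30% decline). Survival is exponential with

```
log h = log h₀ + β_TV (log TV − log 138) + β_resp · 1[true responder]
        + β_low · 1[low expression]
```

with defaults β_TV = log 1.618, β_resp = log 0.378, β_low = 1.0 and
h₀ = ln2 / 13.5 per month — anchored to the clinical effect sizes the
method is meant to detect; h₀ is calibrated once so the *realized*
cohort-level KM median OS is ≈ 15 months under the default effect mix.
Censoring is administrative: C ~ U(0, c_max) with c_max solved by bisection
so the expected censored fraction matches `censoring_rate` (default 0.3,
~60–70% events) — censoring is independent of the event time given
covariates, so Cox estimates are unbiased by construction.

The low-expression subgroup (default 6/33 ≈ 18%, meanSUVmax drawn below
14.3) embodies the confounding mechanism: its *observed* decline factor is
drawn from a strong-decline distribution (`μ = −1.0`) decoupled from the
hazard, no response benefit applies (`true responder = observed responder ∧
high expression`), and β_low raises its hazard — so spurious volumetric
response co-occurs with poor survival. Best PSA decline is tied to the
decline axis through a Gaussian copula with latent correlation chosen so
the honest-cohort Spearman ρ is 0.67; with the confounded subgroup mixed in,
the realized full-cohort rank correlation attenuates (the acceptance script
reports the measured value).

The simulator emulates cohort-scale structure only: no per-lesion imaging
is behind the simulated TV values (the pipeline's imaging mode closes that
loop on small n), no time-varying hazards, no competing risks, no
correlation between baseline TV and expression.

## Replicate designs and problem sizes

Chosen as the package's own verification scale: hazard-ratio recovery uses
n = 500 patients × 200 replicates (mean-bias and CI-coverage checks);
the confounding contrast uses n = 120 patients × 100 replicates per arm —
n = 120 gives the subgroup model ~80% power for HR 0.378 while the diluted
full-cohort effect (mixture HR ≈ 1.1) stays non-significant; the log-rank
type-I-error check uses the 33-patient scale × 200 replicates; oracle
equivalence uses 50 random volumes ≤ 32³ and 100 random survival fixtures.
All replicate streams are seeded and deterministic.

## Pipeline

One config file (YAML/JSON) with exactly one of a `simulation` or `data`
block drives simulate-or-load → segment → metrics → response → analysis;
all randomness flows from a single root seed, and `manifest.json` (config,
seed, package version, row counts) suffices to reproduce every output
byte-identically. The imaging simulation mode renders baseline/interim
phantom pairs per patient (interim lesion radii scaled by the cube root of
the decline factor, so volumes scale linearly) and feeds the *measured*
volumes into the response stage. Stage failures abort with the stage named;
degenerate statistical sub-models inside the analysis stage are recorded
in the report instead.

## Known limitations

- The segmentation assumes lesions are hotter than their surroundings at
  half their own peak; diffuse marrow involvement below the liver threshold
  is invisible — this is a property of the method being studied, and the
  low-expression mechanism exists precisely to probe its consequence.
- The 50% isocontour under strong blur biases volumes slightly upward
  (edge value ≈ (peak + background)/2 sits above half-peak); within a
  2-voxel-FWHM PSF the bias stays well under the 20% tolerance asserted.
- `maxstat` p-values use permutation only; the analytic improved-Bonferroni
  bound is not implemented.
- No PET/CT registration, automatic organ segmentation, or DICOM handling.
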