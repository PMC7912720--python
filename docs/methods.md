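# Methods

## The measurement model

Every vessel is an ordered 3D polyline with a per-point
maximum-inscribed-sphere radius, in a patient-LPS-like frame (+X patient
left, +Z superior). Before any index is computed a centerline is Taubin
smoothed (λ = 0.5, μ = −0.53, 20 iterations, uniform umbrella weights,
endpoints fixed) and resampled at 0.5 mm. The λ|μ two-pass smoother is used
because a single-pass Laplacian of the same strength visibly shrinks curved
vessels (a 64-point circle of radius 10 loses >4% of its radius in 20
iterations; the two-pass filter loses <0.3%). The smoothing parameters and
the 3 mm spur-pruning threshold are package defaults — reasonable values
for MR-scale vessel reconstructions — exposed as arguments everywhere.

Resampling steps equal Euclidean chords, with the chord length solved by
bisection so that `ceil(L/spacing)` steps land exactly on the far endpoint.
Unlike interpolation at uniform source-arc positions, this makes the
output's own arc spacing exactly uniform and the operation idempotent to
floating precision, which stabilises the discrete Frenet estimates.

Curvature at an interior point is the inverse circumradius of the triple
(p_{i−1}, p_i, p_{i+1}) — the discrete osculating circle — and torsion the
signed dihedral angle between consecutive osculating-plane normals divided
by the arc step (positive for a right-handed helix); both are trimmed at
the boundary, and a collinear triple yields κ = 0 with torsion flagged
undefined (reported as 0). On analytic circles and helices at 0.5 mm
spacing both estimators are within 1% of the closed forms.

Index conventions, where the source conventions are ambiguous:

- Tortuosity is reported as `(1 − chord/arc)·100` so a straight vessel
  scores 0; the raw chord/arc ratio is also exposed. The verbal definition
  (chord divided by arc) and the single-digit percentages reported for real
  vessels cannot both hold; the reported magnitudes win.
- The curvature and torsion "%" indices are mean pointwise κ (resp. mean
  |τ|) in mm⁻¹ × 100, which reproduces the magnitude of reported values
  (~0.08 mm⁻¹ → 8%).
- A vessel's diameter is the equivalent diameter 2√(Ā/π) from the
  arc-length-weighted mean cross-sectional area over the whole centerline
  (no single measurement station is specified by the source material).
- The BA bend is the median of |X offsets| of arc-uniform BA samples from
  the confluence→tip chord (computed on an 8× denser resampling so median
  quantisation is ≪ the 0.05 mm reproduction tolerance); the lean is the
  sign of the median signed offset. Because the bend is defined *on the X
  axis*, its magnitude and lean transform with the patient frame; every
  other index is rigid-motion invariant to 1e-9 relative.
- VA dominance: strictly greater than 0.3 mm diameter difference (with a
  1e-9 mm epsilon so an exact boundary pair stays "equal").

Branch labelling is purely geometric: after pruning branches shorter than
the threshold, the network must reduce to one degree-3 junction; the branch
whose free end is most superior (+Z) is the BA, and of the remaining two
the one whose free end lies toward +X is the left VA. Labels are invariant
to input order and traversal direction (tested over all 48 arrangements).

Tube meshes (parallel-transport frames, capped ends, outward winding) give
a divergence-theorem volume that agrees with the centerline integral ∫A ds
to <1% at 64 circumferential segments; this is the internal cross-oracle
for volumes, with `trimesh` as an external check in the tests.

## The twin model

For pair i with members j = 1, 2:

    y_ij = μ + β·x_ij + A_ij + C_i + E_ij

A correlates 1 within MZ and 0.5 within DZ pairs (random mating, no
dominance — the classical-twin assumption; no ADE variant is offered), C is
shared, E independent, all Gaussian. The pair likelihood is bivariate
normal with common variance v = a²+c²+e² and within-pair covariance a²+c²
(MZ) or a²/2+c² (DZ). Sub-models ACE/AE/CE/E fix excluded components at 0;
non-negativity is guaranteed by optimising standardized shares under box
constraints. Fitting concentrates the mean (GLS, scale-free at fixed
correlations) and the total variance (average Mahalanobis form) in closed
form, leaving at most a 2-parameter quasi-Newton problem started from a
Falconer moment estimate (A = 2(rMZ−rDZ), C = 2rDZ−rMZ, clipped) plus
jittered restarts (5 by default). e² is floored at 1e-8 of the phenotype
variance so the covariance stays positive definite. An exhaustive grid
search over the share simplex at 0.001 resolution reproduces the optimum
to <1e-4 log-likelihood on a 30-pair fixture.

The saturated reference frees, per zygosity group, both per-position
variances and the within-pair covariance (6 parameters, Cholesky
parameterised) with the covariate-adjusted mean shared across twin order
and groups. Conventions fixed here because the source material leaves them
open: AIC = −2LL + 2k and BIC = −2LL + k·ln N with N = number of subjects;
model selection is min-AIC with ties broken by BIC then parsimony;
intrapair correlations are one-way ANOVA intraclass correlations on
covariate-adjusted residuals, with Fisher-z intervals at effective n =
pair count; no multiple-testing correction is applied across phenotypes.

Confidence intervals for standardized components are likelihood-profile
intervals: bounds where the profile deviance rises by χ²₁(0.95) = 3.841,
truncated to [0, 1] (a component estimated on the boundary gets a bound of
exactly 0, matching the boundary-touching intervals such tables show).
The profile is exact up to a 1-D search over the remaining-share split.
Against a parametric-bootstrap percentile interval the endpoints agree to
~0.02 on a 1500-pair fixture; at 100–200 pairs the percentile bootstrap is
noticeably left-skewed and the two methods genuinely diverge, which is why
the bootstrap is an oracle, not the default.

Small-sample behaviour worth knowing: the saturated-vs-ACE LRT is slightly
anti-conservative at 100 pairs (≈8% rejection at nominal 5%) and calibrated
by ≈500 pairs (3–6%); and under a pure-E truth, min-AIC selects AE or CE in
≈8% of datasets (the boundary ½χ²₀+½χ²₁ mixture exceeding the 2-point AIC
penalty), so "E everywhere" should not be expected index-by-index even when
it is the truth.

## The synthetic cohort

Defaults are the study-scale conditions: 67 MZ + 33 DZ same-sex pairs;
pair-level age N(49.57, 14.42²) for MZ and N(56.0, 15.23²) for DZ;
P(female) = 0.66; subject-level binary risk factors at prevalences
smoking 0.27, hypertension 0.305, diabetes 0.085, dyslipidemia 0.245,
weekly exercise 0.63, weekly alcohol 0.54. Height is drawn around
sex-specific means (162.9/177.7 cm, SD 6.5) with a twin-correlated
component (0.8 of variance shared, DZ correlation 0.5); BMI similarly
(mean 25.74, SD 4.59, 0.6 shared); weight = BMI·height², so the BMI column
is exactly consistent. Ages are plain Gaussians (no truncation) — they are
covariates, not survival quantities. The 16 default phenotypes are the
measured indices with their published means, SDs where published (SDs for
the percentage indices are package choices of plausible magnitude: 2–5
percentage points), best-model variance shares, and the two consistently
reported covariate effects (smoking and height on the basilar and left-VA
dimensions) with height centred at 167.95 cm so the phenotype means are
preserved.

DZ genetic deviates are built as √0.5·shared + √0.5·own, so the 0.5
correlation is exact by construction, not asymptotic. All randomness
descends from one master seed through named `SeedSequence` spawn keys, so
any stage can be re-run independently and reproduces bit-identical output.

Vessel synthesis works backwards from target indices. The BA is
x = A_x sin(πt), y = A_y sin(2πt) along a chord of length L(1−tort/100) on
+Z: the X amplitude is solved (dense continuum sampling, weighted median)
for the bend, the Y lobe absorbs the remaining arc-length excess for the
tortuosity; a bend needing more arc than the tortuosity allows is an
infeasible-target error, and the attainable minimum tortuosity for a given
bend is exposed. The VAs are circular-helix arcs: radius a = κ/(κ²+τ²) and
pitch b = τ/(κ²+τ²) meet the curvature and torsion targets exactly in
closed form, and the swept angle is solved from the tortuosity (whose
attainable maximum is (1 − τ/√(κ²+τ²))·100 — high torsion at low curvature
caps it; the sampler and the pipeline clip accordingly). Each helix is
placed rigidly with its distal end on the confluence, approaching from
below on its own side of the midline; rigid placement (rather than a
blended transition) is what preserves the closed-form κ and τ through the
measurement pipeline, at the cost of tangent discontinuities at the
confluence, which no index reads. Radii are constant per vessel, so the
equivalent diameter equals its target identically. Round trip: over 100
random physiological target vectors, all length/diameter/tortuosity/
curvature/torsion indices reproduce within 2% relative (worst observed
0.2%) and the bend within 0.05 mm (worst 0.03 mm).

The perturbation model jitters interior points and radii with Gaussian
noise and attaches, with a given probability, one short (<3 mm) spur at a
random interior point — the artifact the pruning stage exists for;
endpoints (hence landmarks) are never moved.

What the generator does *not* emulate: segmentation bias and flow-related
lumen artifacts of TOF-MRA, non-helical VA shapes, radius tapering,
non-Gaussian phenotype distributions, missing members, opposite-sex DZ
pairs, and correlation between geometry noise and phenotype values.
Passing tests therefore show the estimators are correct under the stated
model, not that the model captures every property of real reconstructions.

## Pipeline and reporting

`run_pipeline` executes simulate → measure → model with file-backed stages
(subject CSV with phenotypes; one network per subject; morphometry CSV;
heritability, LRT, covariate-effect, descriptive and Spearman tables).
The geometric phenotypes parameterise the per-subject networks (clipped to
feasible ranges, bend ≤ 0.15·length); BA area, volume and torsion are then
*measured*, i.e. they are derived indices downstream of the simulated ones,
exactly as in a real study. Zygosity descriptives use Welch's t for
continuous variables (pair-level variables such as age counted once per
pair) and chi-square for binaries; at the default sample the age contrast
(49.57 vs 56.0) has ≈50% power at the pair level. The Spearman matrix uses
average-rank ties, emits missing cells for constant variables, and is
rendered as a PNG heatmap. Model 2 adds the configured risk-factor
covariates to the selected Model 1 (age+sex) fit and reports the
likelihood-ratio test (df = number of added covariates, 9 by default) and
Wald effects.

## Sizes used by `scripts/acceptance.py`

Chosen to make Monte-Carlo error small relative to each check's tolerance
on a single CPU: 100 round-trip networks; parameter recovery 4 truth
settings × 50 replicates at 2000 MZ + 1000 DZ pairs (the test suite runs
200 replicates); profile-CI coverage 300 replicates at 500 + 250 pairs
(suite: 500); pure-E selection 150 replicates at 1000 pairs (suite: 200);
saturated-LRT calibration 200 replicates at 500 pairs; plus one full
study-scale pipeline run (67 + 33 pairs). The study-scale quantities
(e.g. the standardized A of BA length at 100 pairs) carry sampling SEs of
roughly ±0.1 and are reported as stochastic outcomes, not point claims.
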