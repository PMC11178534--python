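# Methods

This note documents the models, the numerical choices and the synthetic-data
assumptions behind `retnpi`, and what the test suite does and does not
establish about real ultra-widefield (UWF) angiography data.

## Spherical model eye and area-true pixel measurement

The retina is modeled as a perfect sphere of radius *R* (default 12.0 mm, a
Navarro-style posterior radius; configurable). The fovea sits at the pole of
a fovea-centered coordinate system: a retinal point is (colatitude θ,
azimuth φ), and its geodesic distance from the fovea is *R·θ*. The UWF image
is an azimuthal projection of the imaged spherical cap onto the image plane:

* **stereographic** (default): plane radius ρ ∝ tan(θ/2), projected from the
  point antipodal to the fovea. Conformal; its areal magnification grows as
  sec⁴(θ/2), so equal image pixels cover *less* retina toward the periphery
  (the per-pixel retinal area decays as cos⁴(θ/2)).
* **azimuthal equidistant**: ρ ∝ θ; supports a full-sphere field, which
  stereographic cannot represent (the antipode projects to infinity, so a
  full-sphere stereographic model is rejected as invalid geometry).

The projection scale is set so the largest fovea-centered disc that fits in
the image corresponds to the field's geodesic radius. Retinal areas are
never measured in the image plane: each pixel's four corners are
inverse-projected onto the sphere and the footprint area computed as
*R²* times the spherical excess of the two corner triangles. The excess is
evaluated with the Van Oosterom–Strackee solid-angle formula
2·atan2(|a·(b×c)|, 1 + a·b + b·c + c·a) rather than L'Huilier's theorem:
both are exact for spherical triangles, but the atan2 form is numerically
stable for the extremely thin triangles a pixel footprint produces and
vectorizes over the whole corner grid. Corner-based areas are exactly
additive under grid refinement; pixels whose center falls outside the imaged
disc get area zero, so the summed area approximates the closed-form cap area
2πR²(1 − cos θ_f) with only a boundary-staircase error (measured: ≈ 0.17 %
at 64², ≈ 0.001 % at 512²).

**Zone geometry.** The three retinal zones are geodesic annuli around the
fovea: posterior pole < 10 mm, mid periphery 10–15 mm, far periphery
> 15 mm along the retinal surface. The 10/15 mm radii are interpreted as
geodesic (surface) distances, consistent with area-true DICOM-173-style
measurement, not image-plane distances.

**Field calibration.** The gradable field extent of real UWF angiograms is
device- and montage-dependent. The default field geodesic radius is
calibrated in closed form so the posterior pole occupies 32 % of the imaged
cap — (1 − cos(10/R))/(1 − cos θ_f) = 0.32 gives θ_f ≈ 1.5945 rad, i.e.
19.134 mm at R = 12 — which simultaneously puts the mid and far zones at
34.9 % and 33.1 %, reproducing the reference 32/35/33 split. The calibration
uses only the closed-form cap-area formula; the per-pixel numerical
summation is independent of it and is what the tests check. The field radius
is a plain constructor argument for other devices.

## Guided segmentation

Perfused retina is bright on an angiogram. `levelset_segment` grows
connected components from user seeds over a closed intensity band
[low, high] (band edges inclusive — intensities exactly at the threshold are
perfused), then regularizes the boundary by morphological closing and
opening with a disc of radius `smoothing` (default 1 px; 0 disables it,
which recovers noise-free two-level images exactly). This is a transparent,
deterministic boundary-evolution segmenter in the spirit of level-set VOI
tools; its parameters are exposed rather than asserted as any particular
software's defaults. Everything downstream consumes only the resulting
per-pixel state {perfused, nonperfused, ungradable}, so externally produced
(e.g. manually graded) masks can be substituted via the coded-PNG reader.

Grader corrections operate on pixel regions: positive/negative corrections
of the perfusion label, and of the gradable area (negative marks pixels
ungradable; positive restores the stored automatic state). Artifact
exclusion (eyelash shadows etc.) marks regions ungradable with artifact
provenance; ungradable pixels leave both the numerator and the TA of every
zone. Corrections are idempotent and commute with artifact exclusion on
disjoint regions.

A dialect flag selects **area** mode (pixels weighted by their true retinal
footprint) or **voxel** mode (uniform pixel counts, subject to peripheral
distortion); both arms are computed by the same code path with different
weights.

## NPI, transforms, secondary measures

Per zone, NPI = nonperfused area / zone TA; overall NPI = total nonperfused
area / total TA, which is identically the TA-weighted mean of zone NPIs.
NPI is a proportion in [0, 1] internally and formatted as a percentage at
I/O boundaries. Zones with zero gradable area yield NaN and are excluded
from aggregation. Up to three repeated gradings of one eye/visit are
averaged arithmetically.

Overall and posterior-pole NPIs can be exactly 0, so before modeling they
are transformed by T.NPI = (NPI·(n − 1) + 0.5)/n with n = 20 eyes — a
strictly increasing affine map onto [0.5/n, 1 − 0.5/n] with fixed point 0.5
and an exact inverse; mid- and far-periphery NPIs are left untransformed
(their values are bounded away from 0 in practice). Secondary measures:
logOCT = log₁₀(CST in μm) (270 μm ↔ 2.43); Snellen denominator
20·10^logMAR (logMAR 0.176 ↔ ≈ 20/30); counting-fingers acuity is mapped to
logMAR 1.9 by convention and flagged as a non-numeric source. Intragrader
reliability is the Pearson correlation between first and third repeated
gradings paired per eye/visit with all visits pooled; zone-to-overall
association uses Spearman rank correlation.

## Longitudinal mixed model

The MMRM is a linear mixed model with fixed effects on the piecewise time
basis {min(t, 1), max(t − 1, 0)} — so the two coefficients are directly the
year-1 and year-2 annual rates — plus optional age/sex/dropout covariates,
and random intercepts for patient and for eye-within-patient (two variance
components capturing within-patient longitudinal and inter-eye correlation).
Estimation is REML (statsmodels `MixedLM`, L-BFGS with a Powell fallback);
intervals and the slope-equality contrast are Wald-based; tests are
two-sided at α = 0.05 with no multiplicity adjustment. The piecewise basis
was chosen over categorical time because the target quantities are per-year
rates and a p-value for their difference; a categorical-time fit can be had
by passing factor covariates instead.

Degenerate inputs: if the response is numerically noise-free the mixed
likelihood is singular, so the fitter detects a zero-residual OLS fit first
and returns that exact interpolating solution with zero variance components
(the correct limit). With `random_effects=()` the variance components are
constrained to zero, which makes the fixed effects exactly the OLS solution
on the same design matrix — the property the test suite verifies against a
closed-form least-squares oracle.

Secondary analyses: OD/OS symmetry by exact Wilcoxon signed-rank (exact
null for n ≤ 25 without ties, else normal approximation; all-zero
differences return p = 1 with a flag); normative comparison by tie-corrected
Mann-Whitney U; both are checked against exhaustive enumeration of the null
distribution for small samples. The dropout contrast adds a completer-status
fixed effect to the MMRM and reports the between-group difference ± SE per
response.

## Synthetic data: what it emulates and what it does not

`simulate_truth` builds a nonperfusion *frontier* at geodesic radius *f*:
retina beyond *f* is nonperfused (the centripetal, periphery-first pattern of
progressive ischemic retinopathy), optionally with angular lobes reaching
further in. Caps and sectors have closed-form areas, so each truth region
carries an exact analytic per-zone NPI — e.g. a 12 mm frontier gives
mid-periphery NPI (cos 1 − cos 1.25)/(cos(10/12) − cos 1.25) ≈ 0.630 — used
as the oracle for the full imaging pipeline (agreement within 0.5 NPI
percentage points at 512²). `render_uwf` draws perfused/nonperfused retina
at two intensity levels (default 200/50), near-black artifact wedges, and
seeded Gaussian noise; renderings are pure functions of (arguments, seed).

`simulate_cohort` draws per-eye NPI trajectories (percentage points) from

NPI(i,j,t) = baseline + b_i + c_ij + s₁·min(t,1) + s₂·max(t−1,0) + ε,

with b_i ~ N(0, sd_patient²), c_ij ~ N(0, sd_eye²), ε ~ N(0, sd_residual²),
clipped to [0, 100] with the clip count recorded (a warning fires if > 5 %
of values clip, since truncation distorts the generating structure).
Defaults: 10 patients × 2 eyes, visits 0/1/2 years, s₁ = 7.22, s₂ = −0.69
%/yr, SDs 8/3/2 points. The SDs are chosen to give slope CI widths of the
observed order; true between-patient variability in RVCL-S progression is
unknown, so they are stand-ins, not estimates. The baseline mean is 30 %:
back-calculating a baseline from mean absolute (≈7.2-point) versus mean
relative (≈59 %) year-1 change gives ≈12 %, but that ratio is a
harmonic-type mean dominated by small-baseline eyes; more importantly, with
a between-patient SD of 8 points a 12 % baseline would truncate ≈8 % of
generated values at 0 and bias slope recovery, while at 30 % truncation is
negligible (< 0.1 %) and the cohorts actually carry the stated
variance-component structure. `simulate_dropout` withdraws patients with
probability logistic(−3.0 + 0.08·baseline NPI) (≈35–40 % marginal dropout at
the default baseline, rising with severity) and truncates their visits.

The generator emulates the *statistical* structure the analysis assumes —
spherical geometry, two-intensity perfusion contrast, additive Gaussian
noise, Gaussian random effects, linear-in-time means. It does not emulate
vessel trees, dye-transit phases, leakage, montage seams, registration
error, non-Gaussian grader disagreement, or floor effects near NPI 0/100.
Passing tests therefore demonstrate that the implementation is correct and
unbiased *under its own model assumptions*; they do not validate the
segmentation against human grading of real angiograms.

## Problem sizes and tolerances

Geometry checks run at 256²–512² (cap-area conservation < 0.5 %, projection
round-trip < 0.5 px at 1,000 random pixels); end-to-end imaging recovery at
512² within 2 NPI percentage points; Monte-Carlo slope recovery uses 200
replicate 10-patient cohorts (mean estimate within 2× Monte-Carlo SE of the
generating rates); CI coverage uses 500 replicates (accepted range
90–99 %); exact-test cross-checks enumerate all sign assignments / rank
splits for n ≤ 8. Transform round-trips are exact to 1e-12; partition
conservation to 1e-9 relative in area mode and exactly in voxel mode.

## Known limitations

* The sphere is a first-order retinal shape model; real eyes are aspheric
  and axial length varies between patients. All geometry is configurable
  per eye but no per-patient biometry fitting is provided.
* The field-extent calibration stands in for the unknown true gradable
  extent of any particular device's images.
* Wald intervals from 10-patient cohorts are slightly anticonservative in
  principle; measured coverage at the default design is ≈95–97 %.
  Satterthwaite degrees of freedom are not implemented.
* Interactive level-set VOI evolution is approximated by a
  deterministic seeded region-growing + morphology pipeline; agreement with
  any specific proprietary tool is not claimed.
* Optic-disc modeling is omitted; zones are centered on the fovea only.
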