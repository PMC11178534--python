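# retnpi

Quantification of retinal nonperfusion on ultra-widefield (UWF) fluorescein
angiograms, and mixed-model estimation of its annual rate of change.

`retnpi` is aimed at ophthalmic imaging researchers who track ischemic
retinopathies (RVCL-S, diabetic retinopathy, vein occlusion) with the
**nonperfusion index (NPI)**: the nonperfused retinal area divided by the
total gradable area (TA), per retinal zone and overall. Measuring NPI on UWF
images is geometrically non-trivial — the ~200° field is a projection of a
sphere, so image pixels do not have equal retinal areas — and its
longitudinal analysis must respect the correlation between repeated visits
and between the two eyes of one patient. This package implements the whole
chain:

1. **Spherical model eye** (`eye_geometry`) — the retina as a sphere of
   radius *R* = 12 mm (Navarro-style posterior radius) with the fovea at the
   pole. Images are fovea-centered stereographic (or azimuthal-equidistant)
   projections of the imaged cap. Each pixel's four corners are
   inverse-projected onto the sphere and its true retinal footprint (mm²)
   computed by spherical trigonometry, so area sums are independent of
   peripheral projection distortion. Numerically, the per-pixel sums
   reproduce the closed-form spherical-cap area 2πR²(1 − cos θ) to < 0.5 %.
2. **Geodesic retinal zones** (`npi_metrics`) — posterior pole (< 10 mm),
   mid periphery (10–15 mm) and far periphery (> 15 mm geodesic from the
   fovea). With the default calibrated field extent, the zones occupy
   32 % / 35 % / 33 % of the imaged surface.
3. **Guided segmentation** (`segmentation`) — seeded region growing over an
   intensity band with morphological boundary regularization, plus grader
   positive/negative corrections and eyelash-artifact exclusion (artifact
   pixels become ungradable and leave all area sums).
4. **NPI and transforms** (`npi_metrics`) — per-zone and overall NPI, the
   zero-handling transform **T.NPI = (NPI·(n−1) + 0.5)/n** (n = 20 eyes)
   applied to overall and posterior-pole values before modeling, logOCT =
   log₁₀(CST), logMAR ↔ Snellen conversion, intragrader reliability
   (Pearson) and zone-to-overall Spearman correlations.
5. **MMRM** (`longitudinal_models`) — REML linear mixed model with fixed
   piecewise time basis {min(t, 1), max(t−1, 0)} giving separate year-1 and
   year-2 rates (%/yr), random intercepts per patient and per
   eye-within-patient, Wald CIs, a slope-difference contrast, Wilcoxon
   OD/OS symmetry tests (exact), Mann-Whitney normative comparisons, age/sex
   covariate and subgroup refits, and a completer-vs-dropout contrast.
6. **Synthetic ground truth** (`synthetic_data`) — spherical nonperfusion
   frontiers with exact analytic per-zone NPI (cap-area ratios), rendered
   UWF-like images with stored truth masks, and longitudinal cohorts drawn
   from the same variance-component model the MMRM assumes, with
   severity-dependent dropout.

## Worked example

```python
import retnpi as rn
from retnpi.longitudinal_models import fit_mmrm

# --- imaging arm: truth frontier at 12 mm, render, segment, NPI ---------
model = rn.default_eye_model((512, 512))
truth, analytic = rn.simulate_truth(model, frontier_radius=12.0)
rendered = rn.render_uwf(model, truth, noise_sd=10.0, seed=99)
fr, fc = (int(v) for v in model.fovea_pixel)
mask = rn.levelset_segment(rendered.image, [(fr, fc)], smoothing=1, model=model)
area = rn.pixel_area_map(model)
zones = rn.assign_zones(model, area, mask)
m = rn.compute_npi(mask, zones, area)
print(f"analytic mid-periphery NPI {analytic['mid']:.3f}, recovered {m.npi_mid:.3f}")

# --- longitudinal arm: simulate a 10-patient cohort and fit the MMRM ----
cohort = rn.simulate_cohort(rn.SyntheticCohortSpec(seed=7))
fit = fit_mmrm(cohort, response="npi_overall")
print(f"year-1 rate {fit.slope_year1:+.2f} %/yr  CI [{fit.ci_year1[0]:.2f}, {fit.ci_year1[1]:.2f}]")
print(f"year-2 rate {fit.slope_year2:+.2f} %/yr  CI [{fit.ci_year2[0]:.2f}, {fit.ci_year2[1]:.2f}]")
```

prints

```
analytic mid-periphery NPI 0.630, recovered 0.630
year-1 rate +7.17 %/yr  CI [6.05, 8.29]
year-2 rate -0.61 %/yr  CI [-1.73, 0.51]
```

The first line shows the imaging pipeline recovering the closed-form
cap-area NPI of a 12 mm nonperfusion frontier ((cos 1 − cos 1.25)/(cos 10/12
− cos 1.25) ≈ 0.630) through rendering, noisy segmentation and area-true
summation. The second block shows the mixed model recovering this cohort's
generating rates (7.22 and −0.69 %/yr) within its confidence intervals: a
steep year-1 progression of nonperfusion followed by a year-2 plateau.

A thin CLI wraps the same calls:

```sh
retnpi simulate cohort --seed 7 --out out/
retnpi fit --cohort out/cohort.csv --out out/fit.json
retnpi run --seed 7 --out out/        # simulate + fit + rates table
```

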