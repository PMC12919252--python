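# Methods notes

## Stereological model

Podocyte nuclei are treated as convex particles of true caliper
diameter D sectioned by a slab of true thickness T. A particle is
counted when any part of it intersects the slab, so the effective
sampling height is T + D and the detected count per tuft area
overestimates the numerical density by (T + D)/T; the correction
factor CF = T/(T + D) undoes this. The apparent profile diameter d on
the section mixes full equatorial profiles (centre inside the slab)
with smaller cap profiles (centre overshooting by less than D/2);
solving k·D² + (T − d)·D − d·T = 0 for the positive root recovers D
from the mean d, where the shape coefficient k absorbs the particle
geometry. For perfect spheres k = π/4 makes the inversion exact in
expectation: the mean apparent diameter of sectioned spheres is
E[d] = D(T + (π/4)D)/(T + D), and substituting this into the
quadratic returns D identically. The default k = 0.72 encodes the
mildly non-spherical shape of real podocyte nuclei.

Glomerular volume uses the Weibel–Gomez transform V = A^1.5 · β/d_size
of the mean nonsclerotic tuft profile area, with the sphere
coefficient β = 1.38 and size-distribution coefficient d_size = 1.01
(near-monodisperse assumption). For monodisperse spheres the
transform carries an intrinsic ≈1.1% downward bias (E[A]^1.5 vs
E[A^1.5]); the tests bound it below 2%.

Nuclear volume is computed from the *uncorrected* apparent diameter as
the volume of a sphere of diameter (4/π)d, i.e. 32/(3π²)·d³. Density
(via D and CF) and nuclear volume (via (4/π)d) therefore use two
different diameter corrections; this asymmetry is deliberate and
mirrors standard single-section practice.

All formulas are applied per subject to subject-level summaries (mean
profile area, slide-total tuft area, nucleus count, mean apparent
diameter); cohort means are means of per-subject results, which is not
the same as applying the formulas to cohort-mean inputs (Jensen gap).
Internal units are μm/μm²/μm³ throughout; a thin reporting layer
rescales to ×10⁶ μm³ and ×10⁵ μm³ with one-decimal rounding.

## Histology annotations

The apparent diameter is the equivalent-area circular diameter
2·√(area/π) of the nucleus polygon — the estimator is not fixed by the
field's conventions (max-Feret and mean-Feret are alternatives), and
the equivalent diameter is the common digital-pathology default.
Tuft membership is centroid containment, with boundary-touching
centroids counted inside and overlaps resolved to the largest tuft.
Sclerotic tufts are identified by their annotation label, counted for
the sclerosis percentage, and excluded from area statistics and
nucleus hosting. Subjects whose slide has no usable nonsclerotic tuft
raise a dedicated error and are logged and excluded by the pipeline
runner rather than silently skipped. Coordinates are 0-based pixel
centres converted once to μm at load.

## CT morphometry

Fat is the closed HU interval [−150, −50] (pixels at exactly −150 or
−50 are fat). Region growing keeps 8-connected components touching
any seed — 4-connectivity is available but 8 is the common
radiology-viewer default — and the subsequent morphological closing
uses a disk of radius 2 px ("2 pixels" is ambiguous between radius
and diameter; radius is the default and configurable). The closing
result is re-clipped to the cavity mask so VAT can never exceed the
cavity. VO is inclusive at 100 cm². DICOM input is rescaled by the
stored slope/intercept; NIfTI is assumed pre-calibrated. L3-level
selection and manual mask refinement are human steps: the cavity mask
is an input, not a computation.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the pipeline
sees, not the appearance of real data.

- **Sphere–slab sections** implement the visibility and cap-circle
  geometry exactly, so the closed-form mean E[d] and the count law
  (counts/area = N_v(T + D)) serve as independent oracles. Nuclei are
  perfect spheres; consequently, recovery tests that demand exactness
  use k = π/4, while runs with the podocyte default k = 0.72 can only
  be checked for internal consistency — the 0.72 value encodes
  real-nucleus shape that the simulation deliberately does not model.
- **Slide fixtures** use circular tuft polygons on a grid with profile
  areas from the sphere-section law for lognormal glomerular volumes
  (default mean 2.4×10⁶ μm³, CV 0.3), nucleus counts per tuft from
  the Poisson count law at a target density (default 210 per 10⁶ μm³),
  and polygons whose vertex count is area-corrected so polygon areas
  equal the intended circle areas exactly. No texture, staining
  artefacts, overlapping structures or segmentation error are
  simulated, so recovery tests validate the measurement chain, not
  robustness to annotation noise.
- **CT phantoms** place rectangular fat patches (−90 HU) inside an
  elliptical cavity. Rectangles are invariant under the radius-2 disk
  closing, which is what makes an exact pixel-count ground truth
  possible; real VAT is not rectangular, so the phantom tests the
  thresholding/growing/closing chain, not anatomical realism.
- **Cohorts** draw covariates and morphometrics marginally per group
  (non-VO n = 17, VO n = 35 by default) at the published group means
  and SDs; cross-variable correlations are not modelled beyond (a)
  derived columns (count = density × volume) and (b) a single
  standardized effect β of one morphometric on ΔeGFR, constructed as
  Δ = base_g + β·z(x)·σ + ε with Var(ε) = σ²(1 − β²) so the
  standardized slope equals β and the per-group outcome means hit
  their targets (default −12 / −24 ml/min per 1.73 m², σ = 15). VAT
  is lognormal per group (medians 67 / 170 cm²), truncated at the
  100 cm² boundary so group labels and VAT agree. Seven subjects lack
  12-month follow-up by default, mirroring realistic attrition;
  parameter-recovery experiments use the `homogeneous()` spec (equal
  groups, pooled means, complete follow-up) so the fitted β estimates
  the generating β without between-group confounding.

## Statistical choices

- Levene's test (centre = mean, the classic form) gates at α = 0.05
  between pooled and Welch t tests; the gate's α is a package choice.
- Chi-square is Pearson's without continuity correction; ordinal
  scores use the two-sided Mann–Whitney form of the rank-sum test
  with mid-rank ties.
- ANCOVA is OLS outcome ~ group + BMI + age with estimated marginal
  means at covariate grand means and Wald p-values.
- Propensity matching is logistic on BMI alone, greedy 1:1 nearest
  neighbour without replacement and no caliper; the *smaller* group
  is iterated (in a seeded random order) so every pair is a genuine
  nearest match and the pair count is min(n₁, n₂).
- Standardization z-scores every model variable (including binary and
  ordinal adjusters) with the n−1 SD convention; VAT enters as
  log(VAT) before z-scoring. With this convention the unadjusted
  standardized β is algebraically the Pearson correlation, asserted
  to 10⁻¹⁰ in tests.
- Missingness is complete-case per analysis; ΔeGFR is stored signed
  (negative = loss) with relative ΔeGFR computed per subject; no
  multiple-testing correction is applied.

## Numerical and scale choices

Simulation sizes in the default test run were chosen to keep Monte
Carlo error a small fraction of each tolerance: 10⁵ sphere sections
for the oracle agreement (MC standard error ≈0.06% of the mean vs a
0.5% band), a 5×10⁷ μm² footprint for density recovery (>10⁵ visible
nuclei, Poisson error ≈0.3% vs 3%), 10⁶ draws for the section-law
convergence check (0.3% band), and 200 replicates of n = 500 for
standardized-β recovery (SE of the mean ≈0.003 vs ±0.03). Degenerate
inputs fail loudly: zero tuft area, nonpositive baseline eGFR,
constant columns in z-scoring, seeds outside the cavity, and
rank-deficient ANCOVA designs all raise with a description rather
than propagating NaNs.

## Known limitations

- The shape coefficient k is a fixed input; estimating it from data
  is out of scope, and the sphere-based simulations cannot validate
  k = 0.72 itself.
- Single-slide, single-section design: no guard against section-to-
  section variance or tissue deformation.
- The VAT pipeline assumes an HU-calibrated, motion-free slice and a
  correct cavity mask; subcutaneous fat and L3 auto-detection are not
  handled.
- The cohort generator's missing-copula simplification means joint
  distributions (e.g. sex × VAT within group) are not faithful beyond
  their margins; tests that depend on joint structure construct it
  explicitly.
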