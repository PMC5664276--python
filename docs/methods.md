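# Methods

## The measurement problem

After acute myocardial infarction the necrotic core and the surrounding
inflammatory infiltrate can be made visible with different MR contrast
mechanisms: Gd chelates accumulate in nonviable tissue (hyperintense on
LGE), Mn²⁺ enters viable cardiomyocytes (infarct hypointense on MEMRI),
and iron-oxide nanoparticles taken up by macrophages darken inflamed
tissue (MNP-MRI). The quantity of interest is the *enhancement size*:
the enhanced lesion as a percentage of the LV myocardium on each
short-axis slice. The package implements two geometric estimators of
that percentage plus a histology-analog reference measure, and the
statistics used to compare them across modalities.

## Area-based measurement

1. The myocardial ROI is the annulus between the manually traced (or
   phantom-truth) epicardial and endocardial contours. Rasterization is
   by the even-odd rule at pixel centers, with contour-coincident pixel
   centers counted inside; the endocardial test is likewise inclusive,
   so centers on the endocardial contour belong to the cavity. This
   convention is exactly reproducible by a per-pixel point-in-polygon
   oracle, which the tests exploit.
2. ROI intensities are min–max normalized: v′ = (v − min)/(max − min)
   over myocardial pixels only. A constant ROI is flagged degenerate
   (all values 0.5) and yields an empty lesion rather than a threshold.
3. The normalized values are histogrammed into 256 bins over [0, 1]
   (the 8-bit convention) and Otsu's threshold is computed: over every
   cut between bins, maximize σ_b²(t) = ω₀ω₁(μ₀ − μ₁)² with bin centers
   as class values. Within-class variances are computed directly (not by
   subtraction), so σ_b² + σ_w² = total variance is a checkable
   invariant at every cut.
4. Lesion pixels are those strictly above the threshold for
   hyperenhancing modalities and strictly below for hypoenhancing ones;
   threshold-coincident values always fall to the below class.

**Threshold placement at ties.** When two modes are separated by empty
bins, every cut inside the gap gives the same σ_b², an exact plateau.
Reporting the smallest tied candidate would pin the threshold to the
edge of the gap and make it sensitive to a single stray count; we
instead report the mean of the tied candidates — the plateau midpoint,
landing between the modes — which is equally deterministic and is
mirrored by the exhaustive oracle used in the tests. Near-ties within a
relative 1e-10 of the maximum are treated as exact to keep float noise
in the cumulative sums from breaking genuine plateaus.

## Sector-based measurement

The LV center is the centroid of the endocardial polygon (or of the
cavity component when only a mask is given). Each myocardial pixel is
assigned to sector ⌊θ⌋ of 360, where θ is the pixel-center angle around
the LV center — 0° along +x, increasing counterclockwise in (x, y), the
same convention as the phantom generator; an `angle_offset` rotates the
origin for anatomical alignment. The sector value is the *mean*
normalized intensity of its pixels, which gives smooth radial profiles;
max or median would be noisier or less sensitive, respectively. Otsu runs on the ≤360 sector values with 64 bins — fewer
bins than samples avoids empty-bin artifacts — and the enhancement size
is the percentage of enhanced among valid sectors. Empty sectors (no
myocardial pixel) are excluded from numerator and denominator; more than
25% empty sectors aborts the measurement, since that indicates a center
outside the cavity.

## Midline (histology-analog) measure

Histological infarct size is often reported as a length fraction along
the mid-wall circumference. We emulate it on masks: for each of 3600
angles, the wall is probed along the ray from the LV center, the midline
point is placed at the midpoint radius between the innermost and
outermost myocardial crossing (robust to non-concentric contours), and
the reported value is the percentage of midline samples inside the
lesion among those inside the myocardium. The exact procedure used for
histological length measurements varies between laboratories; this
mid-wall definition is one reasonable reading and is only applied to
ground-truth masks, never to raw intensities.

## Statistics

- **Bland–Altman**: differences d = a − b, bias = mean(d), limits of
  agreement bias ± 1.96·SD(d) with the sample SD (n − 1). Implemented
  from the closed form.
- **Correlation**: Pearson product-moment; Spearman as Pearson on
  average ranks; two-sided p from t = r√((n−2)/(1−r²)) on n − 2 df;
  Pearson 95% CI by Fisher z. Closed forms, validated to 1e-12 against
  exact hand-computed examples.
- **Regression**: OLS closed form with the pointwise CI of the mean
  response, ŷ ± t₀.₉₇₅,ₙ₋₂ · s · √(1/n + (x − x̄)²/Sxx).
- **Modality comparison**: one-way repeated-measures ANOVA with the
  individual slice as the repeated unit (matching per-slice scatter
  plots of such studies); the F statistic comes from the standard
  decomposition SS_total = SS_slices + SS_modality + SS_error and is
  cross-checked against statsmodels' AnovaRM in the tests. Tukey HSD
  uses q = |μᵢ − μⱼ|/√(MS_error/n) with the *within-subject* error term
  and the studentized-range distribution on (n−1)(k−1) df. Shapiro–Wilk
  on the ANOVA residuals is reported alongside rather than used to
  auto-select a test; both Pearson and Spearman are always printed for
  the same reason. Slices within a subject are not independent, so the
  per-slice analysis overstates effective n; subject-level aggregation
  is available by averaging the table before testing.
- The F test's calibration is checked empirically: labels permuted
  uniformly within each slice give an empirical type-I error ≈ 0.05
  (1000 permutations).

## The phantom generator

Each slice is a 256×256 image (matching a 30×30 mm field of view at
0.117 mm/px): background 0.05, annular myocardium 0.5 between
endocardial radius 40 px and epicardial radius 60 px, and wedge lesions
at 0.9 (hyper) or 0.1 (hypo) — a lesion-myocardium contrast of 0.4.
Wedges are defined by start angle, angular span and transmurality
(fraction of wall thickness from the endocardium outward); membership is
evaluated at pixel centers on the half-open interval [start,
start+span). Noise is Rician — the magnitude of the signal plus complex
Gaussian noise, σ = 0.05 per channel by default — because MR magnitude
images follow that distribution; ground-truth masks are taken before
noise.

The default study is 14 subjects × 4 slices × 3 modalities. Per-subject
wedge spans are drawn from a Gaussian copula with equicorrelation
ρ = 0.6 and modality marginals chosen to emulate the enhancement sizes
such studies report: LGE 147° ± 42°, MEMRI 159° ± 54°, and MNP
175.6° ± 36° *before* widening — the MNP wedge is the infarct wedge
widened by a border-zone margin of 15°/side (the inflammatory infiltrate
exceeds the necrotic core), for a realized mean of ≈205.6° (57.1% of the
circumference, vs 40.8% and 44.1% for the infarct modalities). The 15°
margin is a free parameter of the emulation, not an empirically measured
border-zone width. Spans are truncated to [30°, 360°]: permanent
coronary ligation produces a substantial infarct in every animal, and
Otsu thresholding presupposes a bimodal ROI histogram — applying it to a
lesion-free slice returns an arbitrary split of the noise. Slice-level
variation adds N(0, 10°) jitter to span and start angle, shared across
modalities within a slice.

### What the phantom does and does not emulate

It reproduces the geometry (annulus + wedge), the polarity of each
contrast mechanism, magnitude-MR noise, and the between/within-subject
variance structure. It does **not** model contrast kinetics (Gd washout,
Mn uptake, T2* blooming), papillary muscles, partial-volume effects at
oblique wall angles, wall thinning or remodeling, motion, or coil
inhomogeneity. Passing phantom validation therefore demonstrates the
correctness of the measurement and statistics machinery — not that Otsu
thresholding is unbiased on real tissue, where the intensity
distribution is broader and the lesion border is graded.

## Numerical choices and problem sizes

- Noiseless validation uses 20 wedge geometries with spans uniform in
  (30°, 300°); noise robustness uses 50 phantoms at σ = 0.05. With
  256×256 slices these sizes give rasterization-limited accuracy (well
  under 1 percentage point) while the whole validation completes in
  seconds.
- Degenerate inputs fail loudly: empty masks, constant ROIs,
  single-occupied-bin histograms, centers outside the cavity and
  incomplete ANOVA blocks each raise (or warn and drop) with a message
  naming the violated condition.
- Determinism: every stochastic step takes a seed; study generation,
  quantification and reporting are bit-reproducible, which the test
  suite asserts at the checksum level.

## Known limitations

- Enhancement sizes from real scans depend on bin count and
  normalization range; with manual tracing and scanner-specific
  intensity scales, absolute thresholds are not comparable across
  implementations — only the resulting size percentages are.
- The sector method treats each 1° sector as enhanced/not-enhanced;
  sub-sector lesions are all-or-nothing, which bounds its resolution at
  ≈0.3 percentage points.
- The midline measure is defined on masks; applying it to thresholded
  segmentations of noisy images would inherit the segmentation's errors
  along a single circumference and is not exposed.
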