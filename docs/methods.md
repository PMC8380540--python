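# Methods

This note documents the statistical model behind `adiposize`, the
conventions it fixes, the design of the synthetic cohort generator, and
what the test suite does and does not establish about real data.

## The spherical size model

A mature adipocyte is approximated as a sphere. A single measured
parameter therefore determines all others:

* diameter from cross-sectional (great-circle) area: `d = sqrt(4A/π)`;
* area from diameter: `A = (π/4) d²`;
* volume: `V = (π/6) d³`, reported in picolitres with the fixed factor
  1000 µm³/pl;
* surface area: `S = 4A`, because the surface of a sphere is four times
  its largest cross-section.

All conversions are routed pairwise through the diameter so each formula
exists once; round-tripping is exact to floating tolerance. Because the
square root is concave and the cube convex, Jensen's inequality means the
cohort mean diameter is *not* the diameter of the cohort mean area
(`mean(d(A)) < d(mean(A))`), and the cohort mean volume exceeds the volume
of the mean diameter. Conversions must therefore be applied per cell before
averaging, which is what every pipeline stage does.

Histology cross-sections do not always pass through the widest part of the
cell, so histology-derived "diameters" systematically underestimate the
maximal diameter that collagenase-liberated, spherical cells show under
the microscope. The package treats this as a property of the data, not
something to correct; the method-comparison stage quantifies it.

Histology areas outside [200, 16000] µm² are excluded as processing
artifacts. The bounds are kept (inclusive): the exclusion rule is read as
strictly-smaller / strictly-larger, a choice documented here because the
boundary convention is not otherwise determined.

## Descriptor panel

For each subject × depot × method (and for pooled cohorts) the panel
reports n, mean, median, first and ninth decile, interdecile range
(IDR = D9 − D1), skewness, kurtosis, modal size, and a Shapiro–Wilk
normality test. Fixed conventions, chosen so results are bit-stable and
reproducible across environments:

* **Quantiles**: linear interpolation of order statistics with
  h = (n − 1)p + 1 (the common statistical-software default).
* **Skewness / kurtosis**: population central-moment estimators
  g1 = m3/m2^1.5 and m4/m2² (Pearson convention, normal → 3). The Pearson
  convention is used because near-normal collagenase diameter samples
  should sit around 3, which is how cohort kurtosis values in this field
  are normally read.
* **Mode**: argmax of a Gaussian KDE with Silverman bandwidth on a
  512-point grid over [min, max]. Modal size is reported because in
  right-skewed area distributions neither mean nor median coincides with
  the most frequent cell size. No modality testing is attempted.
* **Shapiro–Wilk**: defined for 3 ≤ n ≤ 5000; pooled samples above 5000
  values are subsampled (seeded) for the test only, with a logged note.
  Degenerate inputs do not crash: zero-variance samples report NaN
  skewness/kurtosis and their constant value as mode.
* **QQ tables**: plotting positions (i − 0.5)/n with both axes
  standardized, so a sample of exact normal scores lies on the identity
  line; emitted as tidy tables, not images.
* **Histogram export**: fixed-width bins, default 250 µm² (area) and
  2.5 µm (diameter); widths are configurable since none is canonical.

IDR is linear, so the cohort mean of per-subject IDRs equals
mean(D9) − mean(D1) exactly — a useful internal-consistency check on any
published descriptor table, which the acceptance suite applies.

Equal-representation pooling samples exactly k cells per retained subject
(without replacement, seeded); subjects below k are excluded and named in
the log rather than padded, since padding would overweight sparse samples.

Per-subject subsampling uses the leading entries of one seeded permutation
per subject × depot × method stratum. Consequently a k = 200 sample is
nested inside the k = 500 sample for the same seed — exactly the design the
reduced-cell-count sensitivity analysis assumes — and per-subject draws are
independent of table ordering because the stream is keyed by stable digests
of the stratum labels.

## Method comparison

Subject mean diameters from the two methods are inner-joined on subject
and depot (with depot pooling, a subject contributing both depots counts
twice, matching how such comparisons are usually plotted). Agreement is
summarized by Pearson concordance and Bland–Altman analysis with the
difference fixed as histology − collagenase and limits of agreement at
bias ± 1.96 · SD(differences). The bias is expected negative for the
sectioning reason above; the generator reproduces this and the test suite
asserts the sign on every seeded cohort.

## Associations

* **Correlation matrices**: per-depot Pearson correlations of each subject
  mean size parameter against each continuous phenotype, with
  pairwise-complete deletion (each pair reports its own n, mirroring
  cohort tables in which every lab variable has a different denominator).
  Bonferroni correction uses the family of all *tested* pairs in the
  matrix — pairs with fewer than 3 complete observations are reported as
  untested and excluded from the family size, which is logged.
* **Regression adjustment**: ordinary least squares of a response on the
  mean size plus covariates (BMI, optionally sex and T2D status coded 0/1
  with female / non-T2D reference). Coefficients are reported in raw
  units. Rank-deficient designs fail loudly with the collinear columns
  named.
* **Respirometry**: Pearson correlations of the four respiratory states
  (free OXPHOS, OXPHOS, ETS, leak; pmol O₂·s⁻¹·ng DNA⁻¹) with depot mean
  diameter are reported uncorrected, as is conventional for these small
  paired subsets; BMI-adjusted regression rows are appended when
  phenotypes are available.
* **Cell-count sensitivity**: per subject, the mean diameter from the full
  k cells is compared with the mean from a nested reduced subsample.
  Under the nested design the population correlation has the closed form
  `r = sqrt((σb² + σw²/k_full) / (σb² + σw²/k_reduced))`, which the test
  suite uses as an independent oracle for the simulation.

## Synthetic cohort generator

No per-cell data are deposited for cohorts of this kind, so the generator
emulates the statistical structure the analysis assumes. Defaults encode
the study conditions: 188 subjects; histology availability 161 sc / 188 vc;
collagenase 84 sc / 97 vc; respirometry 24 sc / 35 vc; phenotype marginals
(age 48 ± 13 in [18, 78]; BMI 43.6 ± 13.3 in [18.2, 83.3]; glucose
6.0 ± 3.0; HbA1c 6.0 ± 1.2; cholesterol 5.1 ± 1.0; LDL 3.1 ± 0.8; HDL
1.3 ± 0.4; triglycerides 1.9 ± 1.0 mmol/l, each truncated to its observed
range); 59/188 male; T2D prevalence 45/185 with 3 unknown; per-variable
missing-completely-at-random rates chosen to reproduce the observed
per-variable counts.

**Phenotypes** come from a Gaussian copula: a latent multivariate normal
with unit marginals whose correlation matrix carries the configured
couplings (positive semi-definiteness is validated at construction, with
the most implicated variable pair named on failure), mapped through
truncated-normal inverse CDFs (continuous variables) or thresholds
(sex, T2D). Background phenotype structure (glucose–HbA1c 0.6,
cholesterol–LDL 0.8, HDL–triglycerides −0.3, T2D–glucose 0.45,
T2D–HbA1c 0.55, BMI–HDL −0.15) keeps the marginal joint distribution
clinically plausible without inducing size–lab couplings where none are
configured.

**Histology cells** are truncated lognormal areas on [200, 16000] µm²:
per subject i and depot, log-area ~ N(µ_i, σw²) with
µ_i = µ0 + σb·z_i, where z_i is the subject's latent size factor from the
copula. The size factor is coupled to BMI at r = 0.47 in both depots and —
visceral depot only — to glucose (0.26), HbA1c (0.31) and HDL (−0.32);
subcutaneous lab couplings are exactly zero, so the sc matrix provides a
built-in negative control. The lognormal family is the simplest strictly
positive right-skewed choice; truncation to the artifact filter window
means the filter is also exercised on in-range data. Couplings act at the
subject level because the analysis correlates subject *means* with
phenotypes.

Three parameters are not tabulated anywhere and are **calibrated by
deterministic root-solves** at generation time (values recorded in the
provenance file):

* σw solves: the central subject (z = 0), constrained to the cohort mean
  area, has truncated-lognormal IDR/mean equal to the configured cohort
  ratio (sc 7283.1/3472.0 ≈ 2.10, vc 5635.3/2748.8 ≈ 2.05). This gives
  σw ≈ 1.04 (sc) and 0.99 (vc).
* µ0 solves: the Gauss–Hermite average of per-subject truncated-lognormal
  means over z reproduces the cohort mean area (3472.0 sc, 2748.8 vc µm²).
* σb solves: the quadrature SD of per-subject means reproduces the
  configured between-subject SD (886.8 sc, 863.6 vc µm²). Truncation
  compresses subject-mean dispersion, so σb (≈ 0.38–0.41) is noticeably
  larger than the naive log-CV.

Matching the IDR/mean ratio with a two-parameter family leaves per-subject
skewness overdetermined: generated samples run ≈ 1.6–2.1 versus the
reported 1.1–1.3. The shape *ordering* — skew(diameter) < skew(area) <
skew(volume), all positive — is preserved and is what the invariant tests
assert; matching both dispersion and skewness would need a third shape
parameter and is a known limitation.

**Collagenase diameters** are per-subject normal (truncated at zero), 100
cells per subject. The subject mean is affinely linked to the subject's
*realized* histology mean diameter at the configured inter-method
correlation (0.46) with marginals 105.6 ± 14.7 µm (sc) and 98.3 ± 15.3 µm
(vc); the within-subject SD is set from the configured collagenase IDR
under normality (IDR/2.563, ≈ 25.7 / 23.9 µm). Collagenase means sit
~45 µm above histology means, so the Bland–Altman bias is negative by
construction, as observed with real tissue.

**Respirometry** draws each state as mean + sd·(r·z_d + sqrt(1 − r²)·ε)
with z_d the standardized realized depot mean diameter and the ε terms
sharing a common component (ρ = 0.7) so states are mutually correlated.
Configured couplings: sc −0.41 (free OXPHOS), −0.53 (OXPHOS), −0.59 (ETS),
−0.45 (leak); vc −0.15/−0.36/−0.25/−0.35. State levels (free OXPHOS
0.45 ± 0.15, OXPHOS 1.00 ± 0.30, ETS 1.35 ± 0.40, leak 0.25 ± 0.08
pmol O₂·s⁻¹·ng DNA⁻¹) are plausible values for DNA-normalized mature
adipocyte respiration chosen once; the published analysis reports
correlations, which are scale-free, so the levels affect nothing tested.
The physical ordering ETS ≥ OXPHOS ≥ free OXPHOS ≥ 0 and 0 ≤ leak ≤ OXPHOS
is enforced by clipping afterwards; clip counts (typically ~10 values per
cohort) are logged and recorded in provenance. Clipping attenuates the
configured correlations by well under the sampling noise at n = 24–35.

**Determinism**: all draws descend from one `SeedSequence(seed)` in fixed
stage order; identical seed + config give byte-identical tables.

### What the generator does not emulate

Real histology exhibits section-plane bias, per-slide staining batch
effects, spatially correlated cells within a section, possible small-cell
second populations, and missingness that is unlikely to be completely at
random. None of these are modelled. Passing recovery tests therefore show
that the *analysis pipeline* is correct and well calibrated under the
stated statistical structure — not that the structure is a complete model
of adipose histology. Conclusions about real tissue require real tissue.

## Problem sizes used by the test suite

The recovery suite averages 100 full default cohorts (≈ 210,000 cells
each); the cell-count sensitivity simulation uses 146 subjects × 500 cells
× 100 replicates; normality calibration uses ≈ 2,100 per-subject
collagenase samples across 12 cohorts and one cohort (349 subject×depot
samples) for power. These sizes give Monte-Carlo standard errors a factor
of ~5–10 below the tolerances asserted, while keeping a laptop run of the
whole suite around a minute for the heavy tests.

## Known limitations

* Per-subject skewness/kurtosis of generated areas exceed the reported
  cohort values (see calibration note above).
* The depot availability pattern follows the reported per-depot counts;
  with visceral histology available for all subjects the sc∩vc overlap is
  determined by the sc count and cannot be set independently.
* The truncated-normal marginals keep the *untruncated* mean/SD as
  location/scale, so realized moments shift slightly where truncation is
  asymmetric (e.g. BMI mean ≈ 44.1 rather than 43.6).
* Bonferroni is the only multiplicity correction offered, matching the
  analysis it implements; FDR-style procedures are out of scope.
* Respirometry state levels are plausible but invented; only their
  correlations with size are calibrated.
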