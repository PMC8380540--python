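# adiposize

Distribution-centered analysis of human adipocyte size.

Adipocyte size is reported in at least four interchangeable parameters —
cross-sectional area (histology, µm²), diameter (collagenase-isolated
cells, µm), volume (pl) and surface area (µm²) — linked by the spherical
model `d = sqrt(4A/π)`, `V = (π/6)d³`, `S = 4A`. Because these transforms
are nonlinear, they reshape the size distribution: right-skewed area
distributions become flatter in diameter and sharper in volume, and by
Jensen's inequality the cohort mean of a transformed size is not the
transform of the cohort mean. `adiposize` is for researchers who quantify
fat-cell populations and want the whole distribution, not just a mean: it
provides

* **geometry** — per-cell spherical conversions, the 200–16,000 µm²
  histology artifact filter, and seeded per-subject cell subsampling;
* **panel** — per-subject and equal-representation pooled descriptor
  panels: mean, median, first/ninth decile, interdecile range
  (IDR = D9 − D1), skewness, kurtosis (Pearson, normal → 3), KDE modal
  size, Shapiro–Wilk normality, plus tidy density/histogram/QQ tables;
* **method_compare** — histology vs collagenase agreement on subject mean
  diameters: Pearson concordance and Bland–Altman bias with 1.96·SD limits
  of agreement;
* **association** — per-depot, Bonferroni-corrected Pearson matrices of
  mean size against phenotypes (age, BMI, glucose, HbA1c, lipids) with
  pairwise-complete n bookkeeping, BMI/sex/T2D-adjusted linear regression,
  mitochondrial respirometry associations (free OXPHOS, OXPHOS, ETS, leak
  per ng DNA), and the reduced-cell-count sensitivity analysis;
* **synthcohort** — a seeded Gaussian-copula generator of full synthetic
  studies (phenotypes, per-cell sizes, respirometry) calibrated to
  published cohort summaries, so every stage is testable without access to
  patient data.

See `docs/methods.md` for the model conventions and the generator's
calibration.

## Worked example

Simulate a cohort at the default study conditions (188 subjects, ~500
histology cells per subject and depot, 100 collagenase diameters) and run
the comparisons:

```sh
$ adiposize simulate --seed 42 --out cohort
wrote 227906 cell records for 188 subjects to cohort/

$ adiposize panel cohort/cells.csv --parameter area --out panels
wrote 530 subject panels to panels/

$ adiposize compare-methods cohort/cells.csv --out mc.csv
n=168 bias=-43.73 µm LoA=[-70.10, -17.35] r=0.396

$ adiposize associate cohort/cells.csv cohort/phenotypes.csv --depot vc --out assoc.csv
32 pairs tested (family m=32), 4 significant after Bonferroni; wrote assoc.csv

$ adiposize sensitivity cohort/cells.csv --out sens.csv
r=0.9868 (p=1.49e-127) across 161 subjects; wrote sens.csv
```

The cohort summary (`panels/cohort_summary_area.csv`) reports each
descriptor as mean ± SD across subjects:

```
depot      method  n_subjects  mean_mean  mean_sd  idr_mean  skewness_mean
   sc   histology         161     3491.5    908.1    7152.0            1.7
   vc   histology         188     2783.3    857.4    5595.2            2.1
   sc collagenase          84     8633.4   2153.3   10418.8            0.7
   vc collagenase          97     8282.2   2417.9    9381.4            0.7
```

Histology areas are strongly right-skewed while collagenase-derived
distributions are nearly symmetric. The negative Bland–Altman bias
(−43.7 µm) reflects that histology sections rarely cut a cell at its
widest point, so histology mean diameters run below the diameters of
freed, spherical cells. In the visceral association matrix
(`assoc.csv`, diameter rows):

```
     variable   n  estimate      p  p_adjusted
          bmi 181    0.5472 0.0000      0.0000
      glucose 137    0.2262 0.0079      0.2513
          hdl  90   -0.2813 0.0072      0.2318
```

Mean size tracks BMI strongly; glucose and HDL show the configured
visceral-only couplings (at a single seed they need not survive the
32-test Bonferroni correction — the recovery tests average 100 cohorts).
The sensitivity command shows subject mean diameters are stable when the
per-subject cell count drops from 500 to a nested 200 (r ≈ 0.99 here).

Everything the CLI does is also available as a library:

```python
from adiposize import generate_cohort, bland_altman, describe

cohort = generate_cohort(seed=42)
panel = describe(cohort.cells.query("method=='histology'")["value"])
print(panel.skewness)  # > 0: pooled areas are right-skewed
```

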