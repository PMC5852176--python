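# mibgquant

Quantitation and normal-database analysis for planar cardiac
**¹²³I-MIBG** (metaiodobenzylguanidine) scintigraphy.

¹²³I-MIBG is a norepinephrine analog that images cardiac sympathetic
innervation.  The workhorse quantity is the **heart-to-mediastinum ratio**
(HMR): the mean counts in a circular heart ROI divided by the mean counts
in an upper-mediastinal rectangular ROI on an anterior planar image,
measured *early* (~15 min post-injection) and *late* (3–4 h).  Low HMR and
high myocardial washout predict adverse outcomes in heart failure and
support the differential diagnosis of Lewy body disease.  Two practical
obstacles stand between a raw planar image and a clinically comparable
number, and this package implements both:

1. **Collimator standardization.**  Low-energy collimators suffer septal
   penetration from the 159 keV (and higher) photons of ¹²³I, which
   depresses the measured ratio.  With a phantom-derived conversion
   coefficient `K_i` per camera–collimator, institutional ratios are
   mapped to medium-energy general purpose (MEGP) equivalent conditions:

       HMR_std = (0.88 / K_i) · (HMR_i − 1) + 1

   where 0.88 is the MEGP reference coefficient.  The map is affine,
   order-preserving and fixes HMR = 1.

2. **Washout rates** with decay correction, `DCF = 0.5^(Δt/13 h)`:

       WR_BDC = ((H_E − M_E) − (H_L − M_L)/DCF) / (H_E − M_E) × 100 %
       WR_DC  = (H_E − H_L/DCF) / H_E × 100 %
       WR_HMR = (HMR_E − HMR_L) / HMR_E × 100 %   (standardized ratios)

On top of these sit the normal-database statistics a reference cohort
needs: per-measure mean/SD, empirical 2.5 %/97.5 % reference limits,
Shapiro–Wilk normality checks, OLS age regressions (line displayed only
when p < 0.10), a median-age split with Welch t-test, and "years per
0.1 HMR loss" summaries.

Because the multicenter normal-database images and tables are not
publicly deposited, the package ships a first-class **synthetic-data
module**: a cohort generator emulating a 62-patient normal database (two
collimator sub-cohorts, truncated-normal ages on 20–84 y, a linear
late-HMR-vs-age model, Poisson-scale count noise) and a phantom renderer
producing 256×256 anterior planar count images with a known ground-truth
ratio, collimator point-spread blur, an optional septal-penetration tail
and Poisson noise.  Every pipeline stage is testable end to end against
known truth.

Intended users: nuclear-medicine physicists and methodologists who need a
tested, scriptable reference implementation of HMR standardization and
washout arithmetic, or a simulation bench for ROI/quantitation methods.

## Worked example

```bash
mibgquant simulate --n 62 --seed 7 --out cohort.csv --images imgs
mibgquant quantify --early imgs/P001_early.pgm --late imgs/P001_late.pgm \
                   --seed 150,96 --out counts.csv
mibgquant standardize --cohort cohort.csv --out std.csv
mibgquant washout --cohort std.csv --out wr.csv
mibgquant analyze --cohort wr.csv --out report
```

prints

```
wrote 62 patients to cohort.csv
wrote 124 phantom images to imgs
early HMR 1.90, late HMR 2.31 -> counts.csv
standardized 62 patients -> std.csv
added washout columns for 62 patients -> wr.csv
late HMR vs age: slope -0.0074, r^2 0.087, p 0.020; report in report
```

Reading the output: patient P001 was simulated on a low-energy collimator
(`K_i = 0.55`), so the image-measured institutional HMR of 1.90/2.31
(early/late) is depressed relative to MEGP conditions; `standardize`
lifts it to the MEGP-equivalent scale before any cross-camera statistics.
For this seed the cohort's late standardized HMR declines by 0.0074 per
year of age (r² = 0.087, p = 0.020, so the regression line is displayed),
i.e. roughly 0.07 per decade — about 13 years of aging per 0.1 HMR loss
(`report/report.json`, `age_declines`).  `report/summary.csv` holds the
reference table; for this seed the late standardized HMR is
3.26 ± 0.41 with an empirical 2.5 % lower limit of 2.56, and the three
washout rates average 12.7 % (background+decay corrected), 17.1 % (decay
corrected) and −8.9 % (HMR-based; negative because the late ratio usually
exceeds the early one in normals).

The same operations are available as a library:

```python
import mibgquant as mq

cohort = mq.simulate_cohort(seed=7)
std = mq.standardize_cohort(cohort)
wr = mq.add_washout_columns(std)
report = mq.run_full_analysis(wr, out_dir="report")
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole chain from scratch under the given seed: simulates a
default 62-patient cohort, renders and re-quantifies a subset of phantom
image pairs, standardizes, computes washout rates and writes the full
normal-database report (tables, JSON, figures) under
`results/pipeline/`, plus the JSON result file at the given path.
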