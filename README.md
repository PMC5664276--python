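# lvquant

Quantification of contrast-enhanced myocardial lesions on short-axis
cardiac MR, for small-animal infarct studies that image the same heart
with several contrast mechanisms: late gadolinium enhancement (LGE, the
infarct is *hyper*intense), manganese-enhanced MRI (MEMRI, viable
myocardium takes up Mn²⁺ so the infarct is *hypo*intense), and iron-oxide
nanoparticle MRI (MNP-MRI, phagocytosing macrophages render the inflamed
zone *hypo*intense). Because no raw animal data are redistributable, the
package ships a synthetic phantom generator with analytic ground truth,
so every measurement stage is verifiable end to end.

## What it computes

Given a short-axis slice and the myocardial ROI (epicardial + endocardial
contours or a binary annulus mask), the enhanced lesion size is measured
as a percentage of the LV myocardium in three ways:

- **Area-based.** Myocardial intensities are min–max normalized to
  [0, 1], histogrammed (256 bins), and thresholded with Otsu's method —
  the threshold *t* maximizes the between-class variance
  σ_b²(t) = ω₀ω₁(μ₀ − μ₁)², equivalently minimizes the within-class
  variance. Pixels beyond the threshold (above for hyper-, below for
  hypoenhancement) are the lesion; size = 100 · lesion px / myocardium px.
- **Sector-based.** The myocardium is registered to 360 radial sectors of
  1° around the LV cavity center; each sector carries the mean normalized
  intensity of its pixels, the sector values are Otsu-thresholded
  (64 bins), and size = 100 · enhanced sectors / valid sectors.
- **Midline.** The mid-wall circumference is probed at 3600 angles and
  the lesion fraction along it is reported — the mask-level analog of a
  histological length-based infarct measurement.

Method agreement and modality comparisons use Bland–Altman analysis
(bias ± 1.96 SD limits of agreement), Pearson/Spearman correlation with
Fisher-z intervals, OLS regression with pointwise 95% confidence bands,
and repeated-measures one-way ANOVA with Tukey HSD on the within-subject
error term (Shapiro–Wilk normality reported alongside).

## Worked example

```python
import lvquant as lq
from lvquant.threshold import quantify_area

# 256x256 phantom: annular myocardium (radii 40-60 px) with a transmural
# 90-degree hyperintense wedge
spec = lq.PhantomSpec(wedges=(lq.LesionWedge(start_angle=20, span=90),))
image, truth = lq.generate_phantom(spec)

mask = lq.MyocardialMask(truth.myocardium_mask, lq.lv_center(truth.myocardium_mask))
pct, otsu, lesion = quantify_area(image, mask, "hyper")
print(f"area-based: {pct:.1f}%  (truth {truth.true_fraction_area:.1f}%, "
      f"threshold {otsu.threshold:.3f})")
```

prints

```
area-based: 25.0%  (truth 25.0%, threshold 0.004)
```

— the 90° wedge covers a quarter of the annulus, and on a noiseless
phantom the normalized histogram has only two occupied levels, so the
Otsu threshold sits just above the lower one.

The full study pipeline is driven by the numbered scripts:

```sh
python analysis/01_simulate_study.py    # 14 subjects x 4 slices x 3 modalities
python analysis/02_quantify_lesions.py  # area / sector / midline per slice
python analysis/03_compare_methods.py   # ANOVA, Bland-Altman, correlations
python analysis/04_validate_accuracy.py # phantom-truth validation
```

or by the equivalent CLI (`lvquant simulate|quantify|compare`). On the
default seeded study this reports mean enhancement sizes of ≈42.5%
(LGE), 45.8% (MEMRI) and 57.0% (MNP-MRI), an MNP-vs-infarct difference
significant at p < 10⁻¹⁰ (Tukey), area-vs-sector Bland–Altman biases
within ±0.02 percentage points, and positive cross-modality correlations
(r ≈ 0.7–0.96) — the inflammation zone measuring larger than, and
scaling with, the infarct.

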