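# tdluquant

Automated quantification of **terminal duct lobular unit (TDLU) involution**
from breast-histopathology detections and segmentations.

TDLUs are the milk-producing structures of the breast and the site where
most breast cancers arise. With age and after menopause they regress —
fewer and smaller TDLUs containing fewer acini — and the *degree* of this
involution is inversely associated with breast cancer risk. Assessing
involution manually is labor-intensive and subjective; `tdluquant`
implements the automated alternative: given a slide's tissue mask, adipose
estimate, TDLU instance segmentation and acinus detections, it computes the
standard quantitative and qualitative involution measures, calibrates
automated acinus counts onto the manual counting scale, and provides the
full agreement-statistics toolbox used to validate automated against
manual assessment.

## What it computes

**Five quantitative measures** per slide (densities use the
adipose-adjusted tissue area `A_adj = A_tissue · (1 − f_adipose)`):

| measure | definition |
| --- | --- |
| TDLUs/mm² | `K / A_adj` |
| median TDLU span (μm) | median over TDLUs of `4·√λ_max · res`, the major-axis length of the ellipse with the same normalized second central moments as the TDLU region |
| median acini/TDLU | median of per-TDLU acinus counts, × calibration coefficient (default **3.888**, through-origin regression of manual on automated counts) |
| acini/mm² | all detected acini / `A_adj` |
| median TDLU area (mm²) | median of per-TDLU pixel areas |

**Two qualitative classifications**: per-TDLU Russo lobule types
(type 1 < 12 acini, type 2 = 12–80, type 3 > 80) summarized as the
slide's predominant type, and the Baer slide categories (*no type 1* /
*predominantly type 1 and no type 3* / *mixed*).

**Validation statistics**: point-detection precision/recall/F1 with
one-to-one Hungarian matching within a physical radius, Dice similarity
for segmentations (exactly F1 on pixel sets), ICC(3,1) (two-way mixed,
consistency, single rater) with F-distribution 95% CI, Fleiss' κ with a
large-sample significance test, and wrappers for Spearman /
Mann–Whitney / Kruskal–Wallis / χ² association tests.

Because real whole-slide images cannot be redistributed, the package
includes a **synthetic-slide generator**: pseudo-H&E renders of a tissue
region containing adipose blobs and TDLUs (discs of intralobular stroma
filled with annular acini), each with exact ground-truth masks, points and
measures, plus a deterministic reference segmentation backend, a trainable
per-pixel adipose segmenter, and a simulated manual observer implementing
the ROI / up-to-10-TDLU manual protocol.

## Worked example

```python
from tdluquant import (
    SlideSpec, SlideFrame, generate_slide,
    CalibrationModel, compute_measures, classify_slide,
)

slide = generate_slide(SlideSpec(seed=3))          # 2048² px at 2 μm/px
measures, records = compute_measures(slide.truth, CalibrationModel())
print(f"{measures.n_tdlus} TDLUs, {measures.tdlus_per_mm2:.2f} TDLUs/mm2")
print(f"median span {measures.median_span_um:.0f} um, "
      f"median acini/TDLU {measures.median_acini_per_tdlu:.1f} (calibrated)")
print(classify_slide(records).baer_category)
```

```
12 TDLUs, 1.08 TDLUs/mm2
median span 543 um, median acini/TDLU 64.2 (calibrated)
mixed
```

The 12 planted TDLUs yield a density of 1.08/mm² over the 11.1 mm² of
adipose-adjusted tissue; the median raw count of 16.5 acini/TDLU is
calibrated by 3.888 onto the manual counting scale (64.2), and the mix of
lobule types places the slide in the Baer *mixed* category.

The same pipeline is available from the shell:

```bash
tdluquant simulate --out run/ --seed 7 --n-tdlus 12
tdluquant measure  --run-dir run/ --out out/          # measures.csv + per_tdlu.csv
tdluquant evaluate --pred-dir run/ --truth-dir run/ --out eval.json
tdluquant calibrate --pairs pairs.csv --out calibration.json
```

## Layout

- `tdluquant.slide_model` — frames, masks, point sets, measure containers
- `tdluquant.measures` — the five quantitative measures + calibration
- `tdluquant.qualitative` — Russo/Baer classification, consensus voting
- `tdluquant.agreement` — F1, Dice, ICC(3,1), Fleiss' κ, association tests
- `tdluquant.io_formats` — PNG/TIFF masks, CSV/GeoJSON points, ASAP-XML
  annotations, measures CSV + provenance sidecar, YAML config
- `tdluquant.backends` — reference and learned segmentation backends,
  tile-and-stitch, cross-validation splits
- `tdluquant.synthetic` — slide generator, detection perturbation model,
  simulated manual observer
- `tdluquant.cli` — the `tdluquant` command

See `docs/methods.md` for the model, parameter and design details.
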