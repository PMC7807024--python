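# cvquant

Quantification of corneal vascularisation (CV) in 2-D en-face angiography
images — AS-OCTA or ICGA — with the study-level statistics used to relate
imaging metrics to vascularisation stage, dye leakage and aqueous cytokines.

The cornea is normally avascular; pathological vessel ingrowth is graded
clinically from angiograms. This package implements an automated measurement
pipeline for that problem, aimed at researchers running longitudinal
treatment experiments (e.g. suture-induced CV regressing under anti-VEGF):

1. **Preprocess** — median + Gaussian speckle denoising, white top-hat
   background suppression, log-Gabor phase-symmetry vessel enhancement.
2. **Segment** — a two-phase piecewise-constant active contour whose
   boundary regularizer is the *area of the γ-neighbourhood of the zero
   level set* (an "infinite-perimeter" regularizer that tolerates the
   irregular boundaries of fine vascular networks), on hybrid
   intensity + phase channels; then crop to a region of interest (ROI).
3. **Measure** — skeletonize the binary vessel map to one-pixel centerlines
   and compute, relative to the ROI pixel count `A`:
   - vessel density `VD (%) = 100 · |vessel px| / A`
   - vessel branch area `VBA (%) = 100 · |skeleton px| / A`
   - vessel width `VW = VD / VBA` — mean vessel calibre in pixels.
4. **Analyze** — linear mixed-effects contrasts of metrics across pooled
   ICGA stage groups {1,2} / {3} / {4,5} with a random intercept per eye,
   simple regression of leakage time on VD, a Spearman cytokine × metric
   matrix with below-LOD exclusion, and paired/independent t-tests for
   treatment effects.

Because real study images are rarely shareable, the package ships a
first-class synthetic generator: ground-truthed random vessel trees grown
from the limbal border, gamma-speckle rendering, and whole longitudinal
studies with configurable density trajectories, an inverse-linear
VD–leakage law, and Gaussian-copula cytokine coupling. Every quantitative
claim in the test suite is scored against this ground truth.

## Worked example

```python
from cvquant import (generate_vessel_tree, render_angiogram, RenderParams,
                     ipac_segment, crop_roi, ROIPolygon, compute_metrics)
from cvquant.preprocess import enhance_chain

tree = generate_vessel_tree(target_density=20.0, seed=1)   # ground truth
image = render_angiogram(tree, RenderParams(speckle_shape=20.0), seed=2)
denoised, tophat, phase = enhance_chain(image)
vessel_map, state = ipac_segment(phase, denoised)
cropped = crop_roi(vessel_map, ROIPolygon.full_frame(vessel_map.shape))
m = compute_metrics(cropped)
print(f"true VD {tree.density:.1f}%  measured VD {m.vd:.1f}%  "
      f"VBA {m.vba:.1f}%  VW {m.vw:.2f}")
```

prints

```
true VD 20.0%  measured VD 22.7%  VBA 4.4%  VW 5.19
```

i.e. the segmentation recovers the 20% ground-truth density to within ~3
percentage points. VW overstates the generator's 2–5 px stroke widths
somewhat because crossing strokes merge into wider compound structures
whose skeleton is shorter than the summed centerlines.

The same flow is available from the shell:

```sh
cvquant run --synthetic --outdir out --seed 3   # full demo study
cvquant segment image.tif --roi roi.json --out mask.png
cvquant metrics mask.png --roi roi.json
cvquant analyze out/metrics.csv --outdir out/stats
```

`out/metrics.csv` holds one row per eye-visit (VD, VBA, VW, ROI size,
stage, leakage time, cytokines); `out/stats_report.txt` the stage
contrasts, leakage regression, Spearman matrix and t-tests.

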