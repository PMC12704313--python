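# shgcast

Reconstructing 3D gland morphology from the **negative impression** glands
leave in second-harmonic-generation (SHG) scans of fibrillar collagen.

## The problem

SHG microscopy images fibrillar collagen label-free. In the mouse
endometrium, the collagen-rich stroma surrounds the epithelial uterine
glands, which contain no fibrillar collagen and therefore appear as dark
"holes", often rimmed by a bright, thin **fibrillar collagen cage**. The
stromal scan can thus act as a *mold*: segmenting the SHG-dark gland+lumen
negative space and filling it digitally yields a 3D *cast* of the glands —
**SHG-casting** — with no immunostaining required. Collagen deposition, the
cage, and gland morphology all remodel across the estrous cycle
(proestrus → estrus → metestrus → diestrus), with the brightest, thickest,
most continuous cages in estrus and fragmented, faint cages in diestrus.

`shgcast` implements this workflow end to end for anyone working with
3D multiphoton z-stacks of collagen-rich tissue:

* **imgio** — multi-page TIFF stacks (8/16-bit) with explicit (z, y, x)
  voxel sizes in µm; 16→8-bit conversion.
* **phantom** — a synthetic endometrium generator (speckled stroma, coiled
  multi-lobed glands, cage, lumen, myometrial shell, attenuation, noise)
  with per-voxel ground truth and estrous-stage presets, so every
  downstream stage is testable without microscope data.
* **metrics** — DSC, IoU, exact Hausdorff distance, sensitivity,
  specificity, with pinned conventions and oracle-verified implementations.
* **intensity** — ROI mean intensities, cage/stroma intensity ratio,
  four-direction "compass" cage thickness, global-mean ratio maps, 3D
  fold-change of gland clusters, and the Shapiro–Wilk / Levene / one-way
  ANOVA / Tukey HSD stage-comparison pipeline.
* **casting** — the casting core: per-slice contour rasterization with
  signed-distance interpolation across unannotated slices (the manual
  route), a deterministic classical negative-space segmenter
  (smooth → threshold → morphological closing → complement), and
  single-gland isolation with morphometry.
* **dlseg** — the two-phase learned workflow: annotate every k-th slice,
  train a 2D slice model, complete dense 3D pseudo-labels, train a 3D
  model, and segment held-out scans with sliding-window inference. The
  pixel learners are multiscale-feature random forests that run on one CPU.
* **cli** — a `shgcast` command wiring everything into reproducible,
  config-stamped runs.

## Key quantities

For masks $A$ (prediction) and $B$ (reference):

$$\mathrm{DSC} = \frac{2|A\cap B|}{|A|+|B|},\qquad
\mathrm{IoU} = \frac{|A\cap B|}{|A\cup B|},\qquad
\mathrm{HD} = \max\Bigl(\sup_{a\in A}d(a,B),\ \sup_{b\in B}d(b,A)\Bigr)$$

For a single mask pair the identity $\mathrm{DSC} = 2\,\mathrm{IoU}/(1+\mathrm{IoU})$
holds exactly; a reported (DSC, IoU) pair that violates it must come from
per-item averaging, which is why `aggregate_metrics` exposes both the
per-item mean and pooled-count conventions.

The cage/stroma ratio is the mean of cage-ROI mean intensities divided by
the mean of stroma-ROI mean intensities (means of means, never pooled
voxels); across the estrous cycle it spans roughly 0.87–2.90-fold, peaking
in estrus.

## Worked example

```python
from shgcast import (CastParams, evaluate_masks, generate_phantom,
                     segment_negative_space_classical, stage_preset,
                     truth_negative_space)

truth = generate_phantom(stage_preset("estrus", seed=11))
cast = segment_negative_space_classical(truth.scan, CastParams())
m = evaluate_masks(cast, truth_negative_space(truth))
print(f"DSC {m.dsc:.4f}  IoU {m.iou:.4f}  HD {m.hausdorff:.1f} vox")
```

prints

```
DSC 0.9972  IoU 0.9944  HD 1.0 vox
```

i.e. on an estrus-stage phantom (64×128×128 voxels at 1.0×0.79×0.79 µm,
noise 5 % of the stromal mean) the classical segmenter recovers 99.7 % of
the gland+lumen cast by Dice overlap and its worst boundary error is a
single voxel. The same chain from the shell:

```bash
shgcast simulate --stage estrus --seed 11 --out scan.tif --truth truth.tif
shgcast cast --scan scan.tif --mode classical --out mask.tif
shgcast glands --mask mask.tif --report glands.csv
```

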