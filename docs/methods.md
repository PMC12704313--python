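# Methods

This note records the models, conventions and design choices behind
`shgcast`, and what the synthetic phantoms do and do not establish about
real scans.

## Coordinate and intensity conventions

All volumes are `(z, y, x)`-ordered, 0-based, half-open. Physical voxel
sizes are `(z, y, x)` in micrometres and must always be supplied
(override > TIFF/ImageJ metadata > sidecar YAML > error); the default
phantom sampling, 1.0 µm z-steps with 0.79 µm xy pixels, mirrors typical
multiphoton acquisition of cleared uterine tissue. Scans are 8- or 16-bit;
16→8-bit conversion offers `fixed_range` (linear [0, 65535] → [0, 255],
round-half-up; the default, matching how exported label maps are usually
collapsed) and `min_max`. Binary label maps are written as 0/255 8-bit TIFF
and read back as {0, 1}.

## The phantom generator

The generator emulates the structures an SHG scan of estrous-cycle
endometrium shows. It is the package's test bed: every downstream claim is
measured on phantoms with exact per-voxel ground truth.

**Geometry.** A bright myometrial frame lines the y/x borders
(`myometrium_thickness`, default 6 µm; intensity multiplier 2). An
elliptical lumen channel runs through every slice (half-width 12 µm).
Glands grow as seeded 3D random-walk centerlines from stalks just outside
the lumen (radially outward start, per-step angular noise
`centerline_curvature` = 0.35 rad, step 2 µm, length 30–60 µm), dilated to
tubes of radius 5–7 µm, with 1–3 spherical lobes of radius 6–9 µm stamped
on the distal third. Walks are re-drawn when they would leave the
endometrium; a gland that cannot be placed after a bounded number of
attempts raises an error. Stalks stop a small gap (2 µm) short of the lumen
so individual casts remain separable components; real glands open into the
lumen, and this simplification is deliberate.

**Intensities** (16-bit, arbitrary units). Stroma is `stroma_mean`
modulated by band-limited multiplicative speckle (Gaussian-filtered white
noise at `stroma_texture_scale` = 1.5 µm, sd 0.18, clipped at 0.2) —
fine-grained fibrillar texture. The cage, a shell of `cage_thickness`
around each gland, has pre-noise intensity exactly
`cage_ratio x stroma_mean`, so class-masked or ROI measurements can
recover the generator parameter without bias. Gland interiors and lumen
sit at 5 % of the stromal mean (fibrillar-collagen-free). Optional
depth attenuation is exponential per µm; the default is compensated
(flat), as acquisitions normally ramp laser power with depth. I.i.d.
Gaussian noise (`noise_sd`, default 50 = 5 % of the estrus stromal mean)
is added last and clipped to the bit range.

**Cage fragmentation.** `cage_continuity` is the fraction of the cage
retained; deletion happens in contiguous patches (thresholding a smooth
random field at the matching quantile), and the field is always drawn so
phantoms at one seed differ *only* where patches are deleted — deleted
sets are nested as continuity drops, which is what makes degradation
testable as a monotone property. Deleted patches become collagen-poor
gaps: stroma-class voxels at 10 % of the stromal mean, i.e. nearly as dark
as the holes. This models the documented failure mode of fragmented
(diestrus) cages — the SHG outline is locally absent and the segmentation
bleeds through the gap — rather than a cosmetic thinning. With
stroma-bright material behind every gap, fragmentation would have no
effect and the estrus-vs-diestrus quality ordering would invert.

**Stage presets.**

| stage | cage_ratio | cage_thickness (µm) | cage_continuity | stroma_mean |
|---|---|---|---|---|
| proestrus | 1.6 | 3.0 | 0.9 | 800 |
| estrus | 2.9 | 4.0 | 1.0 | 1000 |
| metestrus | 1.3 | 2.5 | 0.8 | 700 |
| diestrus | 0.9 | 2.0 | 0.5 | 500 |

The cage ratios span the published 0.87–2.90-fold cage/stroma range with
the estrus maximum and sub-unity diestrus; thickness peaks in estrus;
continuity is lowest in diestrus; the stromal signal itself is highest in
estrus and lowest in diestrus while the noise floor is fixed (one
acquisition setting for all stages), so later stages genuinely carry less
contrast. Continuity fractions and stromal means are package defaults —
no quantitative values are published for them — chosen once to reproduce
the reported directional findings.

**What phantoms do not show.** No optical point-spread function or
scattering is simulated: boundaries are voxel-sharp, which favours
unsmoothed thresholding (below) and means the near-perfect phantom Dice
scores bound, but do not predict, performance on real scans. Gland
morphometry (lengths, radii, lobe counts) is qualitative; vasculature,
which also appears as negative space in real scans, is absent.

## Segmentation metrics

Hausdorff distance is the exact symmetric worst case over foreground voxel
centers, computed with Euclidean distance transforms and verified against
an all-pairs oracle; percentile variants (HD95) exist but are never the
default, since the headline convention is the worst case. Default units
are voxels with isotropic spacing 1 (how pixel/voxel distances are
conventionally reported); physical µm units are opt-in and scale each axis
by the voxel size. Both masks empty scores as perfect (DSC = IoU = 1,
HD = 0, sensitivity reported as 1); exactly one empty mask yields HD = +inf
with the ratio metrics still defined. Multi-item aggregation defaults to
the unweighted per-item mean, with pooled confusion counts as the
alternative; only the pooled form preserves DSC = 2·IoU/(1+IoU), which is
also the diagnostic for recognising per-item averaging in reported pairs.

## Intensity quantification

Multi-ROI values are means of per-ROI means, mirroring how repeated manual
measurements are averaged per sample. `auto_place_rois` replaces manual
placement: boxes fully inside one truth class, sampled reproducibly, with
an optional exclusion margin around a mask (stroma ROIs are placed at
least one cage thickness away from the negative space, as stromal
measurements avoid glands). Compass thickness casts four axis-aligned rays
from an interior point, skips the dark interior and measures the first
contiguous at-or-above-threshold run per ray in µm (per-axis spacing);
rays that exit the image first return 0 with a flag, and the default
threshold is Otsu's on the slice since "visually clear boundaries" are not
algorithmic. `ratio_map` divides by the global mean gray value and
guarantees an output mean of exactly 1; any 1–50-fold display clipping is
presentation only.

`cage_fold_change_3d` divides a z-sub-stack by a normalizing mean and
returns the mean normalized value inside a circular gland-cluster ROI.
The original protocol is ambiguous about whether the normalizer is the
ROI-restricted or whole-stack mean; the ROI-restricted reading makes the
statistic identically 1 (it normalizes the measured region by itself), so
the default is the whole-sub-stack mean, which yields the intended
fold-change of the cluster relative to surrounding tissue and reproduces
the estrus > diestrus ordering; `normalizer="roi"` is available and its
degeneracy is noted here deliberately.

Stage comparisons use Shapiro–Wilk per group (skipped with a `None` below
n = 3), Levene centered at the mean, one-way ANOVA, and Tukey HSD adjusted
pairwise p values (statsmodels; cross-checked in tests against an
independent implementation). Groups of n = 3 match the usual
three-uteri-per-stage design; no further multiplicity correction is
layered on top.

## Casting

**Contours.** Polygons are validated (≥ 3 vertices, non-self-intersecting)
and rasterized even-odd, boundary-inclusive: a pixel belongs to the
interior if its center is covered by the closed polygon, plus the traced
edge pixels. Sparse annotated slices interpolate to dense masks by linear
blending of per-slice signed distance fields (inside positive), thresholded
at ≥ 0; annotated slices pass through verbatim, and slices beyond the
first/last annotation copy their nearest annotated slice. A cylinder
annotated on every third slice — the manual-pilot spacing — reconstructs
exactly.

**Classical segmenter.** Deterministic pipeline: optional Gaussian
smoothing (µm, converted per axis); collagen mask at a threshold;
morphological closing with a Euclidean ball (distance-transform based,
edge-padded so the border does not erode); negative space = complement;
drop components under `min_component` voxels. Two defaults differ from
the obvious first choices, for measured reasons: the threshold is the
*lower* of the two 3-class multi-Otsu splits, because these scans have
three intensity populations (dark negative space, stroma, bright
cage/myometrium) and plain two-class Otsu lands between stroma and cage,
flooding the cast with the entire stroma; and `smooth_sigma` defaults to
0 because pre-smoothing mixes the very bright cage across the sharp hole
boundary and systematically erodes the cast by 1–2 voxels — a large Dice
penalty on gland-sized objects — while the closing and minimum-component
steps already absorb speckle. On scans with real optical blur or heavy
shot noise a sigma of 0.5–2 µm is appropriate; everything is a parameter.
An empty collagen mask (threshold above the maximum) raises a "no mold
detected" error rather than returning an all-foreground cast.

**Isolation.** Connected components (6- or 26-connectivity). The lumen is
the component containing a user seed, else the largest component (flagged
as heuristic) — replacing manual scissor edits. Components at or above
`min_component` become gland casts sorted by volume; smaller ones are
counted as removed, and voxel counts partition the foreground exactly.
Descriptors: `principal_length` is the extent of the voxel cloud along its
first principal (SVD) axis in µm; `mean_width` is twice the mean
distance-to-surface over the component's core — voxels whose Euclidean
distance transform is at least 90 % of the component maximum — a cheap
interior proxy that avoids skeletonization, clamped to the principal
length. Touching glands remain one component; no automatic stalk-splitting
rule exists.

## Learned workflow

The two-phase pipeline assembles dense 3D training labels from sparse
manual work: annotate every k-th slice (default 15), train a 2D slice
model, predict the remaining slices (manual slices always pass through
verbatim — the override is exact, never approximate), train a 3D model on
the completed volumes, and segment held-out scans. Splits are by scan,
never by slice, to prevent leakage; validation scans drive snapshot
selection.

The per-pixel learners are random forests over multiscale Gaussian
derivative features (raw intensity plus smoothed intensity, gradient
magnitude and Laplacian at sigmas 1, 2, 4 voxels) — the classic
trainable-segmentation recipe, chosen because it is deterministic under a
fixed seed, CPU-friendly, and strong on texture-vs-darkness
discrimination. "Epochs" are rounds of tree growth (`trees_per_epoch`,
default 10); each round records validation Dice and the returned forest is
truncated to the best round, making snapshot selection a testable contract.
Training pixels are subsampled per item (class-balanced, default 6000 per
slice, 24000 per volume — a volume is ~100 slices, so the 3D learner gets
a proportionally larger budget). Images are z-scored per item before
feature extraction; at 3D inference the *whole scan* is normalized and
featurized once and the sliding windows (50 % steps, mean-blended
probabilities, ties at 0.5 to foreground) share that field — window-local
statistics would make predictions depend on the tiling, which measurably
degraded held-out accuracy. A scan smaller than one window is edge-padded
to a single window.

Workflow reports carry three assessment axes: the 2D model against manual
slices of the test scans, the 3D model against the test scans'
pseudo-labels, and both against dense ground truth (possible only because
the inputs are synthetic — on real data the third axis is what
immunostaining approximates).

## Problem sizes and numerical choices

Default phantoms are 64×128×128 voxels (≈ 1 M voxels, ≈ 64×101×101 µm),
small enough that the full test suite (104 tests, including the complete
8-scan 4/2/2 learned workflow) runs in ~3 minutes and the acceptance
script in ~1 minute on one CPU, while keeping gland, cage and lumen scales
in realistic proportion. Workflow property tests use 48×96×96. Seeds are
explicit everywhere; phantom generation, classical casting and forest
training are bit-reproducible for a fixed seed on one platform.
Tie-breaks: probability exactly 0.5 binarizes to foreground; interpolated
signed distance exactly 0 is foreground; ROI boxes are half-open. The
5-seed/10-seed replicate counts in tests balance statistical safety
against suite runtime.

## Known limitations

Vasculature is neither simulated nor distinguished from glands (beyond
`min_component`), matching the underlying method's own limitation. The
classical segmenter's defaults are tuned to sharp-boundary phantoms;
real scans need the smoothing re-enabled and possibly a fixed threshold.
Phantom morphology is qualitative, so morphometric outputs
(length/width/volume) are verified only on constructed solids, not
against biological measurements. Forest models are not transferable
across intensity scales without per-item normalization, and no
uncertainty calibration of the probability maps is attempted.
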