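# Methods

## Scope and model

`morphoquant` implements the image-quantification layer of a 3D invasion
study: measurement operators (segmentation, shape features, block
reduction, region ratiometry, spot overlap, wound metrics, normalisation)
plus synthetic-scene generators that emulate each input class with full
ground truth. The generators are first-class, tested code: every quantity a
downstream stage estimates is also emitted as truth, so each stage is
validated as a parameter-recovery problem.

## Compactness

The protrusiveness statistic is moment-based:
`compactness = 2π · E[r²] / A`, with `E[r²]` the mean squared pixel distance
from the object centroid and `A` the pixel count. A filled disc scores 1
(continuum value; discretisation keeps it within 0.05), a filled square
π/3 ≈ 1.047, and any radial protrusion raises it monotonically with
protrusion length. The moment-based form is preferred over
`perimeter²/(4π·area)` because it is robust to boundary pixelation — the
perimeter-based form is kept as the separate `form_factor` feature. The
statistic is translation-invariant exactly and rotation-invariant to ≤ 1%
on pixel grids.

## Synthetic scenes: what they emulate and what they do not

* **Acinus time-lapse** — hourly phase-contrast-like frames over 4 days
  (default 96 frames at 1 h). Appearance is dark body + bright halo ring +
  Gaussian noise (σ = 0.03 of the intensity range): enough contrast
  structure to exercise segmentation, with no attempt at photorealistic
  optics. Acini are discs with initial radius 10 px growing at 0.25 px/h;
  invasive acini additionally extend 3 radial capsules (width 5 px) at a
  configurable rate (0 = non-invasive; the invasive examples use 0.5 px/h,
  chosen so protrusion length reaches roughly one cell-body radius per day,
  comparable to protrusive acini in matrix gel). Per-acinus heterogeneity
  (±10% on radius and growth rate, plus mild low-order boundary harmonics)
  provides the population variance a real cohort would show. Ground truth
  records per-frame pixel area, mask compactness, and an analytic maximum
  Feret diameter.
* **Cell scenes** — three archetypes: *round* = disc; *spindle* = tapered
  superellipse with axis ratio 3–4; *spread* = star polygon with solidity
  < 0.9. These are separable in the 7-feature space by construction; a green
  test on the classifier therefore establishes recoverability of clean
  archetypes, not performance on ambiguous real morphologies. The marker
  channel is uniform in the interior with the 5-px periphery scaled by the
  requested enrichment, so the periphery/interior ratio is exact pre-noise.
* **Spot scenes** — the requested fraction of green spots is placed exactly
  on red spot centres and the remainder kept ≥ one spot diameter from all
  red spots, so realised overlap is known to the pixel.
* **Wound series** — per-row wound half-width shrinking at `closure_rate`
  px/h; the invasive flag adds smooth per-row rate boosts (fingering).
  Wound area is monotone non-increasing by construction.
* **Trafficking series** — a per-timepoint simplex of (membrane, cytoplasm,
  juxtanuclear) intensity fractions deposited uniformly into disjoint truth
  regions; total intensity is conserved.

All generators are bit-reproducible under a fixed seed
(`numpy.random.default_rng`).

## Segmentation

Acini: the below-background component (median minus intensity, clipped) is
Gaussian-smoothed (σ = 2 px) and thresholded by Otsu; segmenting the dark
body rather than the absolute deviation avoids annexing the bright halo, so
measured areas track truth within a few percent. A separation guard
(foreground–background mean gap ≥ 4× background spread) makes noise-only
frames yield zero objects, which plain Otsu would not. Holes are filled,
objects under `min_object_area` removed, border-touching objects cleared
when `exclude_border` is set.

Cells: nuclei are segmented first; the body channel is thresholded and cells
recovered by nucleus-seeded watershed on the distance transform, so touching
cells with distinct nuclei split and every cell contains its nucleus.
Border-touching and marker-negative cells are discarded with their nuclei.
The marker-positivity threshold is exposed as configuration with no claimed
default (no principled universal value exists).

Cross-plane matching links objects in consecutive focal planes greedily by
nearest centroid, never beyond 5.0 px, ties broken by smallest distance then
lowest index; unlinked objects stay singletons. Plane selection takes the
max-area plane (ties: lowest plane index) or the feature-wise mean.

## Block metrics: union versus per-frame

Block metrics default to the pixel **union** of each tracked object's masks
across the block, because a single concatenated outline image per block is
what gets measured, and the union captures the cumulative footprint of
transient protrusions; a per-frame **median** alternative is available via
`method="median"`. Trailing blocks with fewer frames than a full block are
computed but flagged `partial` and excluded from the screen's normalisation.
Object tracking assumes sessile objects (greedy centroid linking, 15 px
default gate); full lineage tracking and motion correction are out of scope.

## Region geometry

Signed boundary distance is negative inside the cell; the first inside ring
has distance −1 (boundary pixels count as inside) and the first outside ring
+1. The membrane band [−5, +2] px is then exactly 7 rings ≈ 4.2 µm at the
0.597 µm/px scale fixed by the −2 px = −1.194 µm calibration pair. The
juxtanuclear region — named but not geometrically defined in trafficking
assays — is implemented as a 5-px dilation ring around the nucleus clipped
to the cell. Ratios default to mean/mean ("mean peripheral intensity / mean
total intensity per cell"); sum/sum is available via `stat="sum"`. The
degenerate nucleus-equals-cell case yields an empty, flagged cytoplasm
rather than an error.

## Spot detection and overlap

White top-hat (disk radius 6 px) suppresses diffuse background; Otsu with a
mean + 4σ noise guard binarises; components under 4 px² are dropped. Overlap
is strictly directional (green-in-red) — the symmetric statistic is *not*
assumed, and cells without green spot area are excluded with a flag instead
of contributing 0 or 100.

## Normalisation and statistics

Z-scores use the control's sample (n−1) standard deviation, computed within
each experiment and pooled afterwards, which removes per-batch baseline
shifts. Log2 fold change divides by the in-scope control mean and errors on
non-positive control means. Group tests are one-way ANOVA (for ≥ 2 groups)
and Welch's two-tailed unequal-variance t-test (exactly 2); raw p-values
are reported by default, with Benjamini–Hochberg adjustment available but
off. Heatmap export clips rendered Z-scores to ±3 (marked `clipped` in the
always-written companion CSV) and renders p-values as a greyscale strip.

Because simulated control acini are near-perfect discs, the control's
compactness variance is tiny and Z-scores for shape metrics are very large;
the meaningful claims are the ranking and the ANOVA p-value, not the Z
magnitude. Real cohorts would show larger shape variance and smaller Z.

## Numerical conventions

* Tie-breaks: plane selection → lowest plane; matching → smallest distance,
  then lowest label; classifier ties → round < spread < spindle.
* RWD is clipped to [0, 100]; the t₀ value is 0 by construction; frames
  where the outer density does not exceed the initial wound density are
  flagged undefined (NaN), not dropped silently.
* T_max½ is linearly interpolated between frames; courses that plateau
  below 50% return NaN with `reached=False`.
* Classifier: standardised features + multinomial logistic regression with
  a fixed seed; confidence is the predicted class probability.

## Known limitations

Synthetic scenes have no uneven illumination, no debris, no out-of-focus
blur, no cell division or death, and archetypes far cleaner than real
morphology; green recovery tests bound implementation correctness, not
real-data performance. Segmentation is classical (threshold + watershed);
3D volumetric segmentation and learned backends are out of scope, as are
lineage tracking and membrane-subdomain (microtopology) analysis.
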