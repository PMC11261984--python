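# Methods

`tomopick` performs training-free, prompt-based particle segmentation
and picking in cryo-electron tomograms. A user marks one particle (or a
few) with a 3D point; the package segments each prompted particle into a
3D instance mask, builds a feature descriptor of the prompted category,
searches the whole volume for similar regions, and segments every match,
producing a full-tomogram semantic mask for that category. No model is
trained at any point: all learning-dependent behavior is delegated to
two pluggable 2D backends — a promptable segmenter and a feature
encoder — and the 3D logic around them is deterministic geometry and
linear algebra.

## Cross-plane self-prompting (instance segmentation)

The intuition is that a particle's silhouette changes slowly between
adjacent tomogram slices. Given a point prompt `(z, y, x)`:

1. The three orthogonal planes through the point (YX, ZX, ZY) are
   segmented with the point prompt, giving a 2D mask `M`, a confidence
   image `C`, and the peak-confidence pixel `Q = argmax C` per plane.
2. For each of the six axis directions, the walk moves one slice at a
   time, prompting the segmenter on the next slice with the previous
   slice's `(Q, M)` as a point-plus-mask prompt. The walk stops when the
   new mask's IoU with the previous accepted mask falls below `tau_iou`
   (the inconsistent mask is discarded, because it no longer describes
   the same object), when the segmenter finds nothing, or at the volume
   boundary.
3. The instance mask is the voxel union of the three initial plane
   masks and all accepted propagated masks.

Assumptions: one particle per prompt; particles are roughly convex and
compact, so consecutive cross-sections overlap heavily (IoU well above
`tau_iou`) until near the particle boundary, where the overlap collapses
and the walk halts. Elongated or branched objects propagate too, but
the stopping statistic is calibrated for blob-like particles.

Choices a reader may wonder about:

* IoU is compared between *consecutive accepted* masks, not against the
  initial plane mask, so slow drift in shape is tolerated while abrupt
  inconsistency stops the walk.
* Two empty masks have IoU 0 by definition; an empty mask is also its
  own stop condition, so the degenerate cases terminate cleanly.
* The six directional walks are fully independent (no cross-direction
  re-seeding); if an initial plane finds nothing, the two directions it
  would seed are skipped and the others still run.
* The prompt voxel itself is contained in the final mask whenever the
  initial YX segmentation contains it.

## Tri-view features and the pyramid

Every slice along each of the three axes is percentile-normalized and
encoded into a feature map at the encoder's stride. Each view's maps
are bilinearly upsampled in-plane (align-corners, no interpolation
along the stacking axis) back to slice resolution, rearranged into
`(z, y, x)` voxel order, and channel-concatenated:

    F = [Z, Y, X]  with shape  (D, H, W, 3C).

Every voxel therefore carries appearance evidence from three orthogonal
2D contexts. Pyramid level `F_r` is the block average of `F` over
`r^3` cells (edge cells average their partial extent), so each level's
volume-weighted mean equals the full-resolution mean exactly — the same
averaging semantics the query pooling relies on. The pyramid is pooled
from the upsampled full-resolution features rather than re-encoded at
lower resolution, which keeps every level consistent with `F` by
construction.

## Hierarchical feature matching (category search)

The category descriptor is the masked average pool (MAP) over the
prompted instance masks: the mean feature vector of all voxels covered
by the masks, voxels counted once per mask that contains them. Matching
proceeds coarse to fine over the pyramid (default ratios 16, 8, 4):

1. all cells of the coarsest level are scored by cosine similarity to
   the query;
2. cells scoring at least `tau_sim` form the keep-mask; it is upsampled
   (nearest neighbor) to the next finer level, and only descendants of
   kept cells are evaluated there;
3. after the finest level, the kept cells undergo greedy non-maximum
   suppression on their full-resolution cell centers, and the top `K`
   survivors become new point prompts.

Each proposal is then segmented with the full cross-plane procedure and
the retained instance masks (plus the prompted ones) are unioned into
the semantic mask.

Numerical conventions: cells with an exactly zero feature vector score
0 (featureless background is legitimate, not an error); cosine is
computed in float64 with a per-row multiply-sum so that evaluating a
subset of cells is bit-identical to evaluating all of them — with the
threshold disabled, hierarchical matching reproduces brute-force
full-resolution matching *exactly*, which the tests assert. NMS ties
are broken by lexicographic cell coordinate; the confidence argmax uses
the same rule. If no coarse cell passes `tau_sim`, the single best cell
is kept (and logged) so the run degrades to one proposal chain instead
of silent emptiness.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tau_iou` | 0.5 | adjacent-slice IoU below which propagation stops |
| `tau_sim` | 0.5 | cosine keep threshold per pyramid level |
| `k_top` | 512 | maximum proposals after NMS |
| `ratios` | (16, 8, 4) | pyramid downsampling ratios, coarse to fine |
| `nms_radius` | auto | suppression radius (voxels); auto = mean bounding-box extent of the prompted instances, tying the suppression scale to the measured particle size |
| `min_instance_fraction` | 0.05 | proposals whose instance is smaller than this fraction of the mean prompted-instance size are dropped (the size filter standard in picking tools; removes noise speckles a background prompt can latch onto) |
| `norm_percentiles` | (1, 99) | per-slice clip range before rescaling to [0, 1]; tomographic slice intensities are heavy-tailed |

`tau_iou`, `tau_sim` and `k_top` defaults are the operating point the
method was designed around; the NMS radius and the instance-size floor
are derived from the data at run time rather than fixed, because both
scale with particle size.

## Mock backends

The mock backends replace the foundation models with deterministic
classical operations so the full pipeline is testable on a laptop with
no downloads. They are reference backends in their own right for
bright-blob synthetic data, not approximations of any particular
network's behavior.

**Segmenter.** Threshold at `median + 3 * MAD` of the slice (on a
noiseless slice, where MAD is 0, halfway between median and maximum —
the half-maximum contour of an isolated object), then grow a
4-connected region from the prompt point. A point falling just below
threshold (a noise dip inside a particle) snaps to the nearest
above-threshold pixel within 2 px; without that tolerance, at 3-sigma
contrast roughly 40% of point prompts that are plainly inside a
particle would return an empty mask. With only a mask prompt, the seed
is the mask centroid snapped to the nearest above-threshold pixel and
the grown component must overlap the prompt mask. Confidence is the
normalized distance to the mask boundary, making the peak a stable
interior point.

**Encoder.** Per stride-8 patch: mean of the median-centered smoothed
slice; patch standard deviation and mean gradient magnitude (both
noise-floor subtracted: the per-slice median of the pooled statistic is
removed, so featureless background maps to a near-zero vector); and an
oriented band-pass bank — the slice is filtered with narrow
difference-of-Gaussians bands (center wavelengths 4 and 8 px by
default) and each channel is the patch-mean difference between the
squared +45° and −45° diagonal-derivative responses of the band-passed
image. Two properties make these channels the load-bearing ones:

* they are *signed* and cancel for isotropic content, so broadband
  noise and the roughly circular outlines shared by all particles
  contribute nothing in expectation, while oriented textures drive the
  channel of their frequency band positive or negative;
* because background maps to ~0, a coarse pyramid cell only partially
  covered by a particle still *points in the particle's direction* —
  dilution shrinks the vector but barely rotates it, which is what lets
  a 0.5 cosine threshold survive 16-fold downsampling.

The oriented channels are gain-boosted (default 1000) so they dominate
the pooled query vector; with brightness statistics dominating instead,
any two bright blob categories are nearly parallel in feature space and
no cosine threshold can separate them.

## Synthetic scenes

The generator emulates exactly the aspects of a tomogram the pipeline
exercises: a noisy scalar volume containing compact bright particles of
two categories with known centers and voxel masks. Each particle is a
compactly supported smoothstep profile (1 inside `r − w`, 0 outside
`r + w`, exactly ½ at the nominal radius `r`, edge half-width `w = 2`
voxels in the crowded presets) modulated by a class-specific plane-wave
texture. The two categories of the standard preset differ in size
(radius 6–8 vs 10–12), texture frequency (in-plane wavelengths ≈4 px vs
≈8 px, placed in different encoder octave bands) and texture
orientation (plane waves along the `(1,1,1)` vs `(1,−1,1)` body
diagonals, so their in-plane orientations differ in two of the three
views); both sit at 3-sigma peak contrast over unit Gaussian noise with
25% texture modulation — deep enough that single-pixel statistics are
unreliable, which is the regime the method is for. The standard preset
places 12 small and 8 large particles in a 96³ volume at minimum center
separation 24 (a fixed scene: the preset pins its generator seed).

The sphere preset (one noiseless radius-8 sphere, sharp ½-voxel edge)
is the geometry fixture: the rendered half-maximum contour coincides
with the nominal radius, so mask IoU and the propagation stop index can
be compared against analytic disk geometry.

Not emulated: missing-wedge anisotropy, CTF modulation, tilt-series
artifacts, molecular crowding, structured background (membranes,
filaments), and non-spherical particle shapes. Passing tests on these
scenes demonstrate that the *algorithmic stages* behave as specified —
exact hierarchical filtering, correct propagation and stopping, correct
pooling and suppression — not that the mock backends would segment real
cryo-ET data; on real tomograms the intended backends are the
foundation-model adapters.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
96³ standard scene (20 particles, ~14k finest-level pyramid cells), the
48³ sphere fixture, and twenty random feature fields up to 64³ with 6
channels; a complete one-prompt semantic run takes a few seconds on one
CPU at these sizes. These scales were chosen so every stage, including
the brute-force oracles, runs comfortably on a laptop.

## Known limitations

* Single-prompt picking quality depends on which particle is prompted:
  a small particle near the volume boundary yields a weaker pooled
  query, and precision/recall on regenerated scenes varies (roughly
  0.75–1.0, with occasional worse outliers). Averaging several prompted
  instances stabilizes the query — the multi-prompt path exists for
  exactly this reason.
* Pick localization is quantized to finest-level cell centers (ratio 4
  by default): an off-center cell can win the argmax on a noisy
  particle, costing a match at tolerances near one particle radius. The
  optional centroid pick mode (`SemanticResult.pick_coordinates`) trades
  this for a dependence on instance-mask quality.
* The propagation stop statistic assumes compact particles; thin
  elongated structures stop late along their long axis.
* The mock segmenter's region growing fragments at low SNR (it has no
  shape prior), which lowers instance-mask IoU in noise even when
  picking is unaffected.
* Anisotropic voxel sizes are carried through metadata but not
  compensated during propagation or NMS.
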