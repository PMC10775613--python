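# Methods

## Problem and approach

Ultra-high-speed Scheimpflug recordings of air-puff corneal deformation
(Corvis ST-style videos, natively 576×150 px, 139 frames) show the cornea as
a bright crescent band whose apex flattens and rebounds. Extracting the
corneal contour in every frame is the prerequisite for biomechanical
analysis, but the frames are noisy and no annotated training data exist.

`corneaseg` performs fully unsupervised per-frame semantic segmentation and
turns it into a contour:

1. **SLIC pre-grouping.** Each frame is partitioned into K superpixels by
   localized k-means under the combined distance
   D′ = √((d_c/m)² + (d_s/S)²), with d_c the Euclidean CIELAB color
   distance, d_s the Euclidean pixel distance, m = 10 the compactness and
   S = √(N/K) the grid spacing. Centers start on a grid (perturbed to the
   lowest-gradient pixel of a 3×3 neighborhood), each pixel searches the
   centers of its own and the 8 neighboring grid cells (equivalent to the
   classical 2S×2S window), centers are recomputed as group means for 10
   sweeps, and stray fragments smaller than S²/4 (and any non-largest
   component of a group) are merged into the dominant adjacent group so
   every superpixel is a single 4-connected component.
2. **Unsupervised FCN clustering.** A six-layer, stride-1 fully
   convolutional network (128→64→32→16→8→4 maps; 3×3 and 1×1 kernels
   alternating; batch normalization on every layer; ReLU after layers 1, 3,
   5; softmax over the 4 output maps) is trained *on the frame itself*:
   each epoch predicts per-pixel argmax labels, replaces every pixel's
   label by its superpixel's modal label, and takes an SGD step on the
   improved loss
   **L = L_ce + α·L_fs**, where L_ce is the pixelwise cross-entropy against
   the refined labels and L_fs = |Fs − C| penalizes the distance between
   the shape factor of the corneal-candidate region and the corneal
   constant C = 10 (α = 0.1).
3. **Shared model.** Frame 1 trains from a seeded random (He)
   initialization; every later frame starts from the previous frame's
   trained parameters (including batch-norm statistics). Because adjacent
   frames differ little, warm-started frames typically reach the loss-based
   stopping criterion in one or two epochs and inherit a labeling that is
   robust to transient noise.
4. **Region selection and contour.** 8-connected components of the refined
   label map are scored by the shape factor Fs = L²/(4πS) (perimeter L,
   area S). The component minimizing |Fs − C| is taken as the cornea (ties
   to the larger area), holes are filled, and the ordered closed boundary
   is traced clockwise with a Moore-neighbor walk starting from the
   topmost-then-leftmost boundary pixel.

Accuracy is measured as the overlap error E = 1 − IoU between the
extracted and ground-truth masks.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `n_superpixels` (K) | 400 | grid spacing ≈ 15 px at 576×150 — much smaller than the ~21 px band thickness, so majority relabeling cannot erase the band |
| `compactness` (m) | 10 | weight of color vs spatial distance in D′ |
| `alpha` (α) | 0.1 | weight of the shape-factor loss term |
| `shape_target` (C) | 10 | corneal shape-factor prior; the crescent band's Fs |
| `lr`, `momentum` | 0.1, 0.9 | plain SGD; standard for this unsupervised-FCN family |
| `max_epochs_first`, `max_epochs_warm` | 100, 30 | epoch budgets for cold / warm frames |
| `loss_threshold` | 0.1 | early stop when the improved loss first drops below it; also the efficiency metric (epochs-to-threshold) |
| `min_labels` | 2 | training stops if the refined labeling drops below 2 distinct labels; a full collapse on a cold start is retried with a fresh seed (up to 3 times) |

## Gradient treatment of the shape-factor loss

Fs is computed from hard argmax labels, so L_fs is piecewise constant with
zero gradient almost everywhere. By default it therefore enters the loss
*value* only — steering the early-stopping criterion and the reported loss
— while gradients flow solely through the cross-entropy term. An optional
differentiable surrogate (`shape_factor_gradient=True`) replaces the hard
term with soft area (summed candidate-channel probability) and soft
perimeter (total variation of that probability map) and backpropagates
sign(Fs−C)·dFs through the softmax. The default matches the printed form of
the loss while keeping the training loop well defined.

## Perimeter and shape factor on a pixel grid

The discrete perimeter is the length of the closed Moore-neighbor boundary
trace with Vossepoel–Smeulders corrected chain weights (0.980 per axial
step, 1.406 per diagonal step). The naive 1/√2 weighting overestimates
smooth boundaries by ~5%, which squares to ~10% in Fs and would push a
rasterized disk outside the intended Fs ≈ 1; the corrected weights keep
both a large disk (Fs ≈ 1.08) and an axis-aligned square (Fs ≈ 1.20 vs the
continuous 4/π ≈ 1.27) within a few percent. A single-pixel region is
scored as a unit square (perimeter 4). Regions smaller than 50 px (at
576×150, scaled with frame area) are not considered as corneal candidates,
and components covering ≥ 60% of the top frame border are excluded from
candidacy (the background slab above the cornea can have an Fs accidentally
near C); if exclusion empties the candidate list it is ignored.

## Synthetic data: what it emulates and what it does not

The generator draws the corneal band between two vertically offset
parabolic arcs (apex at the horizontal center, edge sag 30% of the frame
height), constant thickness 21 px at native resolution — chosen so the
band's shape factor sits at ≈ 10 across the whole deformation cycle, i.e.
inside the C = 10 corneal regime the shape prior assumes. The apex
depression follows a raised-sine temporal profile (zero at the first and
last frame, maximal mid-sequence, emulating applanation and recovery) with
a Gaussian lateral profile. Contamination is additive Gaussian noise
(σ = 0.05 by default) plus bright disk-shaped blob artifacts (radius 3–7 px)
placed uniformly at random at least 5 px away from the band — the failure
mode that defeats thresholding and edge-detection baselines. Ground truth
is the clean band mask and its traced boundary.

The phantom is geometric, not physical: intensities are piecewise constant
(no Scheimpflug optics, no depth-dependent shading), the band thickness
does not change during deformation, and noise is white. Passing the
acceptance suite therefore demonstrates the algorithm's mechanics — noise
rejection via pre-grouping and the shared model, shape-prior region
selection, metric correctness — on controlled imagery, not clinical-grade
performance on real recordings.

## Numerical and design choices

- **NumPy network engine.** The FCN and its backward pass are implemented
  directly in NumPy with channels-first activations; 3×3 convolutions are
  lowered to a single matrix product via a channels-first im2col whose
  copies run along full image rows. All parameters and activations are
  float32 (float64 is used in the gradient-check tests). Batch
  normalization uses the current frame's statistics during training (batch
  of one image, ε = 1e-5); running statistics are tracked with momentum 0.1
  and travel with the shared model.
- **Determinism.** All randomness flows from explicit seeds
  (`numpy.random.default_rng`); two runs with the same configuration are
  bit-identical, which is how the repeatability tests can assert exact
  equality rather than the weaker statistical repeatability reported for
  the clinical setting.
- **Tie-breaking.** Argmax labeling and superpixel majority votes break
  ties toward the lowest label index; region selection breaks |Fs − C| ties
  toward the larger area.
- **Failed frames.** A frame with no selectable corneal region (or a warm
  frame that collapses to one label) is marked failed and scored E = 1 in
  summaries; the pipeline continues, and only an all-frames failure raises.
- **Activations.** ReLU is the default; LeakyReLU and Mish are provided for
  the ablation configuration. The "Pish" variant has no standard published
  definition we could locate, so it is implemented as the smooth
  self-gated form x·σ(x).
- **Scale of the shipped experiments.** The acceptance experiment uses 5
  synthetic videos of 20 frames at the native 576×150 resolution; the
  warm-vs-cold efficiency and repeatability suites run the same protocol on
  192×48 frames (5 frames, 5 videos, 3 repeats) — the properties under test
  are scale-free comparisons between the two initialization modes.

## Known limitations

- Clinical Scheimpflug frames have intensity gradients, specular
  reflections and eyelash shadows the phantom does not model; the C = 10
  prior and the top-border background rule are tuned to the crescent
  geometry and may need adjustment for other instruments.
- The unsupervised objective can, rarely, collapse on a cold start;
  re-seeding handles it in practice but the first frame of a video remains
  the least reliable (the warm-start chain then propagates from whatever
  the first frame found).
- The contour is pixel-accurate, not sub-pixel; downstream biomechanical
  quantities needing sub-pixel apices should fit a curve to the returned
  contour points.
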