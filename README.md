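# corneaseg

Unsupervised corneal contour extraction from dynamic corneal-deformation
videos (air-puff / ultra-high-speed Scheimpflug recordings of the
Corvis ST type).

Corneal biomechanics — keratoconus screening, glaucoma work-ups, refractive
surgery planning — starts from the corneal contour in every frame of a
deformation video. Manual annotation is impractical and classical edge
detectors (Otsu, Roberts, Sobel, Canny) are easily corrupted by the bright
noise these recordings contain. `corneaseg` extracts the contour without
any training labels:

1. each frame is pre-grouped into SLIC superpixels under the combined
   color/spatial distance D′ = √((d_c/m)² + (d_s/S)²);
2. a six-layer stride-1 fully convolutional network clusters the pixels of
   that single frame by alternating argmax label prediction, superpixel
   majority refinement and SGD on the **improved loss**

   L = L_ce + α·L_fs,  L_fs = |Fs − C|,  Fs = ‖L‖²/(4πS),

   the pixelwise cross-entropy plus a shape-factor prior that anchors the
   corneal region near the cornea-specific constant C = 10 (α = 0.1);
3. a **shared model** warm-starts every frame's network from the previous
   frame's trained parameters, exploiting inter-frame continuity to
   converge in a couple of epochs and to resist transient noise;
4. the connected region whose shape factor is nearest C is selected as the
   cornea and its ordered boundary is traced (Moore-neighbor walk).

Accuracy is reported as the overlap error E = 1 − IoU against ground-truth
masks. Because no public deformation videos exist, the package ships a
synthetic-video generator (a deforming bright crescent band with Gaussian
noise and bright blob artifacts, plus per-frame ground truth) that every
stage is developed and tested against. See `docs/methods.md` for the model
details and the phantom's limitations.

The network engine is implemented directly in NumPy (single-image batch
normalization, manual backprop, CPU-only); no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from corneaseg import SyntheticConfig, generate_video, CornealContourExtractor

# a 10-frame noisy deformation video at the native 576x150 resolution
cfg = SyntheticConfig(n_frames=10, noise_sigma=0.05, n_blob_artifacts=5, seed=1)
video, gt = generate_video(cfg)

ext = CornealContourExtractor(random_state=0).fit(video)
print("mean IoU:", round(ext.score(video, gt.masks), 4))
print("epochs per frame:", ext.epochs_used_)
print("contour points, frame 0:", len(ext.contours_[0]))
```

Output:

```
mean IoU: 0.9981
epochs per frame: [13, 1, 1, 1, 1, 1, 1, 1, 1, 1]
contour points, frame 0: 1190
```

The first (cold-started) frame needs 13 epochs to drive the improved loss
below 0.1; every warm-started frame inherits the previous frame's
parameters and converges almost immediately — the efficiency gain the
shared model is for. The extracted masks overlap the ground truth almost
completely (mean overlap error E ≈ 0.002).

The same pipeline is available from the shell:

```bash
corneaseg simulate --n-frames 20 --noise-sigma 0.05 --blobs 5 --seed 1 --out video/
corneaseg extract  --input video/ --seed 0 --out pred/
corneaseg evaluate --pred pred/ --truth video/ --out report.csv
corneaseg benchmark --videos 3 --frames 8 --noise 0.02,0.08 --seed 1 --out bench.csv
```

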