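"""scikit-learn style estimator wrapping the full extraction pipeline."""
from __future__ import annotations

from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .config import SlicConfig, TrainConfig
from .pipeline import evaluate_video, iou, process_video
from .synthetic import GroundTruth, VideoSequence
from .region import extract_contour

__all__ = ["CornealContourExtractor"]


class CornealContourExtractor(BaseEstimator):
    """Unsupervised corneal contour extraction with a shared model.

    Fits a per-frame unsupervised FCN segmentation (SLIC-refined cluster
    labels, shape-factor-augmented loss) over an entire deformation video,
    warm-starting each frame's network from the previous frame's trained
    parameters, and extracts the corneal region mask and contour of every
    frame.  No annotations are used; ``fit`` is the inference process.

    Parameters
    ----------
    n_superpixels, compactness, slic_iters:
        SLIC pre-grouping: number of superpixels K, the compactness m of
        the combined distance D' = sqrt((d_c/m)^2 + (d_s/S)^2), and the
        number of assignment/update sweeps.
    alpha:
        Weight of the shape-factor loss term |Fs - C| added to the
        pixelwise cross-entropy.
    shape_target:
        The cornea-specific shape-factor constant C.
    lr, momentum:
        SGD hyperparameters of the per-frame training loop.
    max_epochs_first, max_epochs_warm:
        Epoch budgets for the cold-started first frame and warm-started
        subsequent frames.
    loss_threshold:
        Early-stopping loss value (training stops when the improved loss
        first drops below it).
    min_labels:
        Training also stops if the refined label count falls below this.
    activation:
        'relu' (default), 'leaky_relu', 'mish' or 'pish'.
    shape_factor_gradient:
        Use the differentiable soft shape-factor surrogate instead of the
        (zero-gradient) hard term.
    warm_start_frames:
        If False, every frame is trained from a fresh random
        initialization (the cold-start baseline).
    random_state:
        Seed for all random initialization.

    Attributes
    ----------
    masks_ : (n_frames, H, W) bool array of extracted corneal masks
        (failed frames all-False).
    contours_ : list of Contour (None for failed frames).
    failed_frames_ : list of frame indices where extraction failed.
    epochs_used_, epochs_to_threshold_ : per-frame training effort.
    result_ : the underlying :class:`VideoResult`.

    Examples
    --------
    >>> from corneaseg import SyntheticConfig, generate_video
    >>> video, gt = generate_video(SyntheticConfig(n_frames=3, seed=0))
    >>> ext = CornealContourExtractor(random_state=0).fit(video)
    >>> ext.score(video, gt.masks)  # mean IoU against ground truth
    """

    def __init__(
        self,
        n_superpixels: int = 400,
        compactness: float = 10.0,
        slic_iters: int = 10,
        alpha: float = 0.1,
        shape_target: float = 10.0,
        lr: float = 0.1,
        momentum: float = 0.9,
        max_epochs_first: int = 100,
        max_epochs_warm: int = 30,
        loss_threshold: float = 0.1,
        min_labels: int = 2,
        activation: str = "relu",
        shape_factor_gradient: bool = False,
        warm_start_frames: bool = True,
        random_state: Optional[int] = None,
    ):
        self.n_superpixels = n_superpixels
        self.compactness = compactness
        self.slic_iters = slic_iters
        self.alpha = alpha
        self.shape_target = shape_target
        self.lr = lr
        self.momentum = momentum
        self.max_epochs_first = max_epochs_first
        self.max_epochs_warm = max_epochs_warm
        self.loss_threshold = loss_threshold
        self.min_labels = min_labels
        self.activation = activation
        self.shape_factor_gradient = shape_factor_gradient
        self.warm_start_frames = warm_start_frames
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _configs(self):
        train = TrainConfig(
            alpha=self.alpha,
            shape_target=self.shape_target,
            lr=self.lr,
            momentum=self.momentum,
            max_epochs_first_frame=self.max_epochs_first,
            max_epochs_warm=self.max_epochs_warm,
            loss_stop_threshold=self.loss_threshold,
            min_labels=self.min_labels,
            seed=0 if self.random_state is None else int(self.random_state),
            activation=self.activation,
            shape_factor_gradient=self.shape_factor_gradient,
        )
        slic = SlicConfig(
            n_superpixels=self.n_superpixels,
            compactness=self.compactness,
            n_iter=self.slic_iters,
        )
        return train, slic

    @staticmethod
    def _as_video(X) -> VideoSequence:
        if isinstance(X, VideoSequence):
            return X
        arr = np.asarray(X)
        if arr.ndim == 4 and arr.shape[-1] == 3:
            arr = arr.mean(axis=-1)
        if arr.ndim != 3:
            raise ValueError(
                f"expected (n_frames, H, W) or (n_frames, H, W, 3), got {arr.shape}"
            )
        if arr.dtype == np.uint8:
            arr = arr.astype(np.float32) / 255.0
        return VideoSequence(frames=np.asarray(arr, dtype=np.float32))

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Run the shared-model pipeline on a video.

        Parameters
        ----------
        X : VideoSequence or array (n_frames, H, W[, 3]) with values in [0, 1]
        y : ignored (unsupervised)
        """
        video = self._as_video(X)
        train_cfg, slic_cfg = self._configs()
        result = process_video(
            video, train_cfg, slic_cfg, warm_start=self.warm_start_frames
        )
        self.result_ = result
        h, w = video.height, video.width
        masks = np.zeros((video.n_frames, h, w), dtype=bool)
        contours: List = []
        for fr in result.frames:
            if fr.mask is not None:
                masks[fr.frame_index] = fr.mask
            contours.append(fr.contour)
        self.masks_ = masks
        self.contours_ = contours
        self.failed_frames_ = [f.frame_index for f in result.frames if f.failed]
        self.epochs_used_ = [f.epochs_used for f in result.frames]
        self.epochs_to_threshold_ = [f.epochs_to_threshold for f in result.frames]
        self.loss_ = [f.final_loss for f in result.frames]
        self.n_frames_ = video.n_frames
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the per-frame corneal masks."""
        return self.fit(X).masks_

    def score(self, X, y) -> float:
        """Mean IoU of the fitted masks against ground-truth masks ``y``.

        Failed frames score 0.  ``X`` is accepted for API compatibility; it
        must be the video the estimator was fitted on.
        """
        if not hasattr(self, "masks_"):
            raise RuntimeError("estimator is not fitted")
        y = np.asarray(y, dtype=bool)
        if y.shape != self.masks_.shape:
            raise ValueError(f"shape mismatch: {y.shape} vs {self.masks_.shape}")
        vals = []
        for pred, true in zip(self.masks_, y):
            vals.append(0.0 if not pred.any() else iou(pred, true))
        return float(np.mean(vals))

    def evaluate(self, gt: GroundTruth):
        """Attach per-frame overlap errors and summaries from ground truth."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        return evaluate_video(self.result_, gt)
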