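"""Per-video orchestration, evaluation metrics and baseline harness.

The shared-model pipeline processes a deformation video frame by frame:
the first frame trains the FCN from a cold (random) initialization, and
every subsequent frame warm-starts from the previous frame's trained
parameters, exploiting the small inter-frame change of the corneal region
to converge in far fewer epochs and to resist transient noise.

Accuracy is scored by the overlap error

    E = 1 - IoU = 1 - |S ∩ G| / |S ∪ G|

between the extracted corneal mask S and the ground-truth mask G: E = 0
for a perfect extraction, E = 1 for disjoint regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import morphology as skmorph

from .config import SlicConfig, TrainConfig
from .network import NetworkState, init_network
from .region import (
    Contour,
    connected_regions,
    extract_contour,
    select_corneal_region,
)
from .segmenter import DegenerateSegmentationError, train_frame
from .superpixel import pregroup
from .synthetic import GroundTruth, VideoSequence

__all__ = [
    "FrameResult",
    "VideoResult",
    "iou",
    "overlap_error",
    "process_video",
    "evaluate_video",
    "run_baselines",
    "summarize_baselines",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class UndefinedMetricError(ValueError):
    """IoU of two empty masks is undefined."""


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Intersection over union |S∩G| / |S∪G| of two binary masks."""
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    union = int(np.logical_or(pred, true).sum())
    if union == 0:
        raise UndefinedMetricError("IoU undefined: both masks are empty")
    inter = int(np.logical_and(pred, true).sum())
    return inter / union


def overlap_error(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Overlap error E = 1 - IoU."""
    return 1.0 - iou(pred_mask, true_mask)


@dataclass
class FrameResult:
    """Outcome of processing a single frame."""

    frame_index: int
    failed: bool
    mask: Optional[np.ndarray] = field(default=None, repr=False)
    contour: Optional[Contour] = field(default=None, repr=False)
    final_loss: Optional[float] = None
    epochs_used: int = 0
    epochs_to_threshold: Optional[int] = None
    overlap_error: Optional[float] = None


@dataclass
class VideoResult:
    """Per-frame extraction results plus evaluation summaries."""

    frames: List[FrameResult]
    network_state: Optional[NetworkState] = field(default=None, repr=False)
    mean_E: Optional[float] = None
    std_E: Optional[float] = None
    mean_IoU: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": [f.frame_index for f in self.frames],
                "failed": [f.failed for f in self.frames],
                "E": [f.overlap_error for f in self.frames],
                "final_loss": [f.final_loss for f in self.frames],
                "epochs_used": [f.epochs_used for f in self.frames],
                "epochs_to_threshold": [f.epochs_to_threshold for f in self.frames],
            }
        )


def _epochs_to_threshold(history: List[float], threshold: float) -> Optional[int]:
    """1-based epoch index at which the loss first dropped below threshold."""
    for i, loss in enumerate(history):
        if loss < threshold:
            return i + 1
    return None


def process_video(
    video: VideoSequence,
    cfg: Optional[TrainConfig] = None,
    slic_cfg: Optional[SlicConfig] = None,
    warm_start: bool = True,
) -> VideoResult:
    """Run the full shared-model extraction pipeline on one video.

    Frame 1 trains from a cold seeded initialization (with up to 3 re-seeded
    retries on label collapse); frames t >= 2 warm-start from frame t-1's
    trained parameters (set ``warm_start=False`` for the per-frame cold
    baseline).  Each frame's refined label map is reduced to the corneal
    region by shape-factor selection, holes are filled, and the ordered
    boundary contour is traced.  A frame with no selectable corneal region
    is marked failed and the pipeline continues; if every frame fails a
    RuntimeError is raised.
    """
    cfg = cfg or TrainConfig()
    slic_cfg = slic_cfg or SlicConfig()
    if video.n_frames < 1:
        raise ValueError("video must have at least one frame")
    results: List[FrameResult] = []
    prev_state: Optional[NetworkState] = None
    for t in range(video.n_frames):
        frame = video.frames[t]
        part = pregroup(frame, slic_cfg=slic_cfg)
        cold = prev_state is None
        if cold:
            state0 = init_network(cfg, seed=cfg.seed + 104729 * t)
            max_epochs = cfg.max_epochs_first_frame
            retry_seed = cfg.seed + 104729 * t + 1
        else:
            state0 = init_network(cfg, warm=prev_state)
            max_epochs = cfg.max_epochs_warm
            retry_seed = None
        fr = FrameResult(frame_index=t, failed=False)
        try:
            state, labels, history = train_frame(
                frame, part, state0, cfg, max_epochs=max_epochs,
                cold_retry_seed=retry_seed,
            )
        except DegenerateSegmentationError:
            fr.failed = True
            results.append(fr)
            continue
        fr.final_loss = history[-1] if history else None
        fr.epochs_used = len(history)
        fr.epochs_to_threshold = _epochs_to_threshold(
            history, cfg.loss_stop_threshold
        )
        regions = connected_regions(labels)
        if not regions:
            fr.failed = True
        else:
            chosen = select_corneal_region(regions, cfg.shape_target)
            mask = ndimage.binary_fill_holes(chosen.mask)
            fr.mask = mask
            fr.contour = extract_contour(mask)
        results.append(fr)
        if warm_start and not fr.failed:
            prev_state = state
        elif not warm_start:
            prev_state = None
    if all(f.failed for f in results):
        raise RuntimeError("corneal region extraction failed on every frame")
    return VideoResult(frames=results, network_state=prev_state)


def evaluate_video(result: VideoResult, gt: GroundTruth) -> VideoResult:
    """Score a processed video against ground truth (in place).

    Per-frame overlap error E (failed frames scored E = 1), then
    mean/std of E and mean IoU = 1 - mean E over all frames.
    """
    if result.n_frames != gt.masks.shape[0]:
        raise ValueError(
            f"frame count mismatch: {result.n_frames} vs {gt.masks.shape[0]}"
        )
    errors = []
    for fr, true_mask in zip(result.frames, gt.masks):
        if fr.failed or fr.mask is None:
            fr.overlap_error = 1.0
        else:
            fr.overlap_error = overlap_error(fr.mask, true_mask)
        errors.append(fr.overlap_error)
    errors = np.asarray(errors)
    result.mean_E = float(errors.mean())
    result.std_E = float(errors.std())
    result.mean_IoU = 1.0 - result.mean_E
    return result


# ---------------------------------------------------------------------------
# classical baselines (library operators + minimal mask post-processing)

def _largest_component(mask: np.ndarray) -> np.ndarray:
    comp, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask
    sizes = np.bincount(comp.ravel())[1:]
    return comp == (int(np.argmax(sizes)) + 1)


def _baseline_mask(frame: np.ndarray, method: str) -> np.ndarray:
    """Best-effort corneal mask from a classical operator.

    Otsu: global threshold, largest bright component, holes filled.  Edge
    operators (Roberts/Sobel/Canny): binarized edge map, dilated, holes
    filled, largest component.
    """
    if method == "otsu":
        thr = skfilters.threshold_otsu(frame)
        mask = frame > thr
    else:
        if method == "roberts":
            edges = skfilters.roberts(frame)
            mask = edges > skfilters.threshold_otsu(edges)
        elif method == "sobel":
            edges = skfilters.sobel(frame)
            mask = edges > skfilters.threshold_otsu(edges)
        elif method == "canny":
            mask = skfeature.canny(frame, sigma=2.0)
        else:
            raise ValueError(f"unknown baseline {method!r}")
        mask = ndimage.binary_dilation(mask, structure=skmorph.disk(2).astype(bool))
    mask = ndimage.binary_fill_holes(mask)
    return _largest_component(mask)


BASELINES = ("otsu", "roberts", "sobel", "canny")


def run_baselines(
    video: VideoSequence, gt: GroundTruth, methods=BASELINES
) -> pd.DataFrame:
    """Score classical threshold/edge baselines per frame against ground truth.

    Returns a long DataFrame with columns ``method``, ``frame``, ``E``.
    Purely a comparison harness around standard library operators.
    """
    rows = []
    for method in methods:
        for t in range(video.n_frames):
            mask = _baseline_mask(video.frames[t], method)
            try:
                e = overlap_error(mask, gt.masks[t])
            except UndefinedMetricError:
                e = 1.0
            rows.append({"method": method, "frame": t, "E": e})
    return pd.DataFrame(rows)


def summarize_baselines(df: pd.DataFrame) -> pd.DataFrame:
    """One row per method: mean and std of the overlap error."""
    return df.groupby("method")["E"].agg(["mean", "std"]).reset_index()
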