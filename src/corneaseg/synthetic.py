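"""Synthetic corneal-deformation video generator with ground truth.

Emulates an air-puff Scheimpflug recording: a bright crescent-shaped corneal
band between two parabolic arcs on a dark background.  Over the sequence the
apex is depressed and rebounds (applanation and recovery) following a
raised-sine temporal profile that is zero at the first and last frame and
maximal near the middle.  Frames are contaminated with additive Gaussian
noise and disk-shaped bright blob artifacts placed away from the band; the
ground-truth mask is the clean band only.

This is a geometric phantom, not a biomechanical model: intensities are
piecewise constant, the band thickness is fixed, and Scheimpflug optics are
not simulated.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import SyntheticConfig, ConfigurationError
from .region import Contour, extract_contour

__all__ = [
    "VideoSequence",
    "GroundTruth",
    "generate_video",
    "write_video",
    "read_video",
]


@dataclass(frozen=True)
class VideoSequence:
    """Ordered stack of grayscale frames, float32 in [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame_rgb(self, t: int) -> np.ndarray:
        """Frame ``t`` replicated to 3 channels for the RGB-input network."""
        return np.repeat(self.frames[t][..., None], 3, axis=-1)


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame binary corneal masks and their ordered boundary contours."""

    masks: np.ndarray  # (n_frames, height, width) bool
    contours: List[Contour] = field(compare=False)


def _band_top_profile(cfg: SyntheticConfig, t: int) -> np.ndarray:
    """Row coordinate of the band's upper edge for every column at frame t."""
    x = np.arange(cfg.width, dtype=np.float64)
    cx = (cfg.width - 1) / 2.0
    apex_row = cfg.apex_row_frac * cfg.height
    sag = cfg.edge_sag_frac * cfg.height
    curvature = sag / cx**2
    base = apex_row + curvature * (x - cx) ** 2
    if cfg.n_frames > 1:
        depth = cfg.apex_depression_max * np.sin(np.pi * t / (cfg.n_frames - 1)) ** 2
    else:
        depth = 0.0
    sigma = cfg.width / 8.0
    return base + depth * np.exp(-((x - cx) ** 2) / (2.0 * sigma**2))


def _band_mask(cfg: SyntheticConfig, t: int) -> np.ndarray:
    top = _band_top_profile(cfg, t)
    rows = np.arange(cfg.height, dtype=np.float64)[:, None]
    return (rows >= top[None, :]) & (rows < top[None, :] + cfg.band_thickness)


def _place_blobs(
    frame: np.ndarray, band: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator
) -> None:
    """Stamp bright disk artifacts outside a safety margin around the band."""
    if cfg.n_blob_artifacts == 0:
        return
    h, w = frame.shape
    margin = 5
    forbidden = ndimage.binary_dilation(band, iterations=margin)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_blob_artifacts):
        for _attempt in range(100):
            r = float(rng.uniform(3.0, 7.0))
            cy = float(rng.uniform(r, h - 1 - r))
            cx = float(rng.uniform(r, w - 1 - r))
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            if not (disk & forbidden).any():
                np.maximum(frame, np.where(disk, cfg.blob_intensity, 0.0), out=frame)
                break


def generate_video(cfg: SyntheticConfig) -> Tuple[VideoSequence, GroundTruth]:
    """Generate a corneal-deformation-like video with per-frame ground truth.

    Deterministic under ``cfg.seed``.  With ``noise_sigma=0`` and
    ``n_blob_artifacts=0`` the band region equals the ground-truth mask
    exactly (mid-intensity thresholding recovers it pixel-for-pixel).
    """
    if not isinstance(cfg, SyntheticConfig):
        raise ConfigurationError("cfg must be a SyntheticConfig")
    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((cfg.n_frames, cfg.height, cfg.width), dtype=np.float32)
    masks = np.empty((cfg.n_frames, cfg.height, cfg.width), dtype=bool)
    contours: List[Contour] = []
    for t in range(cfg.n_frames):
        band = _band_mask(cfg, t)
        if not band.any() or band[-1].any():
            raise ConfigurationError("band leaves the frame")
        frame = np.full(
            (cfg.height, cfg.width), cfg.background_level, dtype=np.float64
        )
        frame[band] = cfg.band_level
        _place_blobs(frame, band, cfg, rng)
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        np.clip(frame, 0.0, 1.0, out=frame)
        frames[t] = frame.astype(np.float32)
        masks[t] = band
        contours.append(extract_contour(band))
    return VideoSequence(frames=frames), GroundTruth(masks=masks, contours=contours)


def write_video(
    video: VideoSequence,
    gt: Optional[GroundTruth],
    path,
    cfg: Optional[SyntheticConfig] = None,
    multipage_tiff: bool = False,
) -> None:
    """Write frames (and masks) to disk plus a JSON sidecar.

    Default layout: ``frame_%04d.png`` (8-bit grayscale), ``mask_%04d.png``
    (0/255), ``meta.json`` with the generating configuration and seed.
    With ``multipage_tiff=True`` the stacks go to ``frames.tif`` /
    ``masks.tif`` instead.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames8 = np.round(video.frames * 255.0).astype(np.uint8)
    if multipage_tiff:
        import tifffile

        tifffile.imwrite(path / "frames.tif", frames8, photometric="minisblack")
        if gt is not None:
            tifffile.imwrite(
                path / "masks.tif",
                gt.masks.astype(np.uint8) * 255,
                photometric="minisblack",
            )
    else:
        for t in range(video.n_frames):
            Image.fromarray(frames8[t]).save(path / f"frame_{t:04d}.png")
            if gt is not None:
                m = (gt.masks[t].astype(np.uint8)) * 255
                Image.fromarray(m).save(path / f"mask_{t:04d}.png")
    meta = {"n_frames": video.n_frames, "height": video.height, "width": video.width}
    if cfg is not None:
        meta["config"] = cfg.to_dict()
        meta["seed"] = cfg.seed
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def _to_float_frames(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim == 4:  # RGB pages -> grayscale
        stack = stack.mean(axis=-1)
    if stack.dtype != np.float32:
        stack = stack.astype(np.float32) / float(np.iinfo(stack.dtype).max)
    return stack


def read_video(path) -> Tuple[VideoSequence, Optional[GroundTruth]]:
    """Read a video written by :func:`write_video`.

    Accepts a directory of ``frame_*.png`` files (with optional
    ``mask_*.png``), a directory holding ``frames.tif``/``masks.tif``, or a
    multi-page TIFF file directly.  Contours are re-traced from the masks.
    """
    path = Path(path)
    masks = None
    if path.is_file() and path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = _to_float_frames(tifffile.imread(path))
    elif (path / "frames.tif").exists():
        import tifffile

        frames = _to_float_frames(tifffile.imread(path / "frames.tif"))
        if (path / "masks.tif").exists():
            masks = np.asarray(tifffile.imread(path / "masks.tif")) > 127
    else:
        frame_files = sorted(path.glob("frame_*.png"))
        if not frame_files:
            raise FileNotFoundError(f"no frame_*.png or frames.tif under {path}")
        frames = np.stack(
            [np.asarray(Image.open(f), dtype=np.float32) / 255.0 for f in frame_files]
        )
        mask_files = sorted(path.glob("mask_*.png"))
        if mask_files:
            masks = np.stack([np.asarray(Image.open(f)) > 127 for f in mask_files])
    video = VideoSequence(frames=frames)
    gt = None
    if masks is not None:
        gt = GroundTruth(masks=masks, contours=[extract_contour(m) for m in masks])
    return video, gt
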