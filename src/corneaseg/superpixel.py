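"""SLIC superpixel pre-grouping.

Pixels are grouped into K spatially contiguous, color-homogeneous
superpixels {S_k} by localized k-means under the combined distance

    D' = sqrt((d_c / m)**2 + (d_s / S)**2)

with d_c the Euclidean CIELAB color distance, d_s the Euclidean pixel
distance, m the compactness (default 10) and S = sqrt(N/K) the grid
spacing.  Cluster centers start on a regular grid (perturbed to the lowest-
gradient pixel in a 3x3 neighborhood), each pixel is assigned to the nearest
center searched within a 2S x 2S window, centers are updated as group
means, and stray fragments are finally merged into adjacent groups so every
superpixel is one connected component.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .config import SlicConfig, ConfigurationError

__all__ = [
    "LabPixel",
    "SuperpixelPartition",
    "rgb_to_lab",
    "color_distance",
    "spatial_distance",
    "combined_distance",
    "pregroup",
]


@dataclass(frozen=True)
class LabPixel:
    """A pixel's CIELAB color components plus its (x=col, y=row) position."""

    l: float
    a: float
    b: float
    x: float
    y: float


@dataclass(frozen=True)
class SuperpixelPartition:
    """Per-pixel superpixel index map realizing {S_k}, k = 0..K-1."""

    labels: np.ndarray  # (H, W) int32, values in [0, K)
    K: int
    grid_spacing: float
    energies: np.ndarray = field(default=None, compare=False, repr=False)

    @property
    def shape(self) -> tuple:
        return self.labels.shape


def rgb_to_lab(frame: np.ndarray) -> np.ndarray:
    """CIELAB conversion (D65) of an RGB frame with values in [0, 1]."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB frame, got shape {frame.shape}")
    return skcolor.rgb2lab(frame)


def color_distance(p, q) -> np.ndarray:
    """Euclidean CIELAB distance d_c between pixels (or arrays of triples)."""
    pl = np.asarray([p.l, p.a, p.b]) if isinstance(p, LabPixel) else np.asarray(p)
    ql = np.asarray([q.l, q.a, q.b]) if isinstance(q, LabPixel) else np.asarray(q)
    return np.sqrt(((pl - ql) ** 2).sum(axis=-1))


def spatial_distance(p, q) -> np.ndarray:
    """Euclidean pixel-coordinate distance d_s."""
    pxy = np.asarray([p.x, p.y]) if isinstance(p, LabPixel) else np.asarray(p)
    qxy = np.asarray([q.x, q.y]) if isinstance(q, LabPixel) else np.asarray(q)
    return np.sqrt(((pxy - qxy) ** 2).sum(axis=-1))


def combined_distance(d_c, d_s, m: float, S: float) -> np.ndarray:
    """Compactness-normalized distance D' = sqrt((d_c/m)**2 + (d_s/S)**2)."""
    if m <= 0 or S <= 0:
        raise ConfigurationError("compactness m and grid spacing S must be > 0")
    d_c = np.asarray(d_c, dtype=np.float64)
    d_s = np.asarray(d_s, dtype=np.float64)
    return np.sqrt((d_c / m) ** 2 + (d_s / S) ** 2)


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    return frame


def _init_centers(lab: np.ndarray, S: float):
    """Grid-initialized centers [l, a, b, x, y], perturbed off gradients.

    Returns the centers in row-major cell order plus the grid shape
    (ny, nx), so center ``iy * nx + ix`` belongs to grid cell (iy, ix).
    """
    h, w = lab.shape[:2]
    gy, gx = np.gradient(lab[..., 0])
    grad = gy**2 + gx**2
    ys = np.arange(S / 2.0, h, S)
    xs = np.arange(S / 2.0, w, S)
    centers = []
    for cy in ys:
        for cx in xs:
            r, c = int(round(cy)), int(round(cx))
            r = min(max(r, 1), h - 2) if h > 2 else min(r, h - 1)
            c = min(max(c, 1), w - 2) if w > 2 else min(c, w - 1)
            if 1 <= r < h - 1 and 1 <= c < w - 1:
                win = grad[r - 1 : r + 2, c - 1 : c + 2]
                dr, dc = np.unravel_index(np.argmin(win), win.shape)
                r, c = r - 1 + dr, c - 1 + dc
            centers.append([lab[r, c, 0], lab[r, c, 1], lab[r, c, 2], c, r])
    return np.asarray(centers, dtype=np.float64), len(ys), len(xs)


def pregroup(
    frame: np.ndarray,
    n_superpixels: int = 400,
    compactness: float = 10.0,
    n_iter: int = 10,
    slic_cfg: Optional[SlicConfig] = None,
) -> SuperpixelPartition:
    """Partition a frame into SLIC superpixels under the D' metric.

    Grayscale frames are replicated to 3 channels before Lab conversion.
    The returned partition covers every pixel exactly once and each group is
    one connected component; ``energies`` records the mean squared D' per
    assignment sweep (non-increasing up to the windowed search and the final
    connectivity enforcement).
    """
    if slic_cfg is not None:
        n_superpixels = slic_cfg.n_superpixels
        compactness = slic_cfg.compactness
        n_iter = slic_cfg.n_iter
    rgb = _as_rgb(frame)
    h, w = rgb.shape[:2]
    n_pixels = h * w
    if n_superpixels < 2:
        raise ConfigurationError("n_superpixels must be >= 2")
    if n_superpixels > n_pixels:
        raise ConfigurationError(
            f"n_superpixels ({n_superpixels}) exceeds pixel count ({n_pixels})"
        )
    lab = rgb_to_lab(rgb)
    S = float(np.sqrt(n_pixels / n_superpixels))
    centers, ny, nx = _init_centers(lab, S)
    K = len(centers)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    m2 = compactness**2
    S2 = S * S
    # localized search: each pixel considers the centers of its own grid
    # cell and the 8 neighboring cells (covers the standard 2S x 2S window)
    gy = np.minimum((yy / S).astype(np.int32), ny - 1)
    gx = np.minimum((xx / S).astype(np.int32), nx - 1)
    labels = np.full((h, w), -1, dtype=np.int32)
    energies = []
    for _ in range(n_iter):
        dist = np.full((h, w), np.inf)
        labels.fill(-1)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                cy_idx = gy + dy
                cx_idx = gx + dx
                valid = (
                    (cy_idx >= 0) & (cy_idx < ny) & (cx_idx >= 0) & (cx_idx < nx)
                )
                k_idx = np.clip(cy_idx, 0, ny - 1) * nx + np.clip(cx_idx, 0, nx - 1)
                c = centers[k_idx]  # (H, W, 5)
                d2 = (
                    ((lab - c[..., :3]) ** 2).sum(axis=-1) / m2
                    + ((xx - c[..., 3]) ** 2 + (yy - c[..., 4]) ** 2) / S2
                )
                better = valid & (d2 < dist)
                dist[better] = d2[better]
                labels[better] = k_idx[better]
        energies.append(float(dist.mean()))
        # update centers as group means of [l, a, b, x, y]
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=K).astype(np.float64)
        feats = np.stack(
            [lab[..., 0].ravel(), lab[..., 1].ravel(), lab[..., 2].ravel(),
             xx.ravel(), yy.ravel()],
            axis=1,
        )
        sums = np.zeros((K, 5))
        for j in range(5):
            sums[:, j] = np.bincount(flat, weights=feats[:, j], minlength=K)
        nonempty = counts > 0
        centers[nonempty] = sums[nonempty] / counts[nonempty, None]

    labels = _enforce_connectivity(labels, K, S)
    # compact label values to [0, K') after merging may have emptied groups
    uniq, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(h, w).astype(np.int32)
    return SuperpixelPartition(
        labels=labels,
        K=int(len(uniq)),
        grid_spacing=S,
        energies=np.asarray(energies),
    )


def _enforce_connectivity(labels: np.ndarray, K: int, S: float) -> np.ndarray:
    """Merge stray fragments so each superpixel is one connected component.

    Components smaller than S**2/4 — and any non-largest component of a
    label — are relabeled to the most frequent neighboring superpixel.
    """
    labels = labels.copy()
    h, w = labels.shape
    min_size = S * S / 4.0
    struct = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    for _pass in range(3):
        changed = False
        for k in range(K):
            mask = labels == k
            if not mask.any():
                continue
            comp, n = ndimage.label(mask, structure=struct)
            if n == 1 and mask.sum() >= min_size:
                continue
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1 if sizes.max() >= min_size else -1
            objs = ndimage.find_objects(comp)
            for cid in range(1, n + 1):
                if cid == keep:
                    continue
                sl = objs[cid - 1]
                r0 = max(0, sl[0].start - 1)
                r1 = min(h, sl[0].stop + 1)
                c0 = max(0, sl[1].start - 1)
                c1 = min(w, sl[1].stop + 1)
                frag = comp[r0:r1, c0:c1] == cid
                ring = ndimage.binary_dilation(frag, structure=struct) & ~frag
                neighbor_labels = labels[r0:r1, c0:c1][ring]
                neighbor_labels = neighbor_labels[neighbor_labels != k]
                if neighbor_labels.size == 0:
                    continue
                vals, cnts = np.unique(neighbor_labels, return_counts=True)
                labels[r0:r1, c0:c1][frag] = vals[np.argmax(cnts)]
                changed = True
        if not changed:
            break
    return labels
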