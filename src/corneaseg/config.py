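"""Configuration dataclasses shared across the pipeline.

Defaults mirror the native Scheimpflug recording geometry (576x150 frames,
139 frames per video) and the method's standard constants: superpixel
compactness m = 10, shape-factor target C = 10, loss weight alpha = 0.1,
early-stop loss threshold 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


ACTIVATIONS = ("relu", "leaky_relu", "mish", "pish")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic corneal-deformation video generator.

    The generator draws a bright crescent band (the cornea in a Scheimpflug
    slit image) between two vertically offset parabolic arcs on a dark
    background.  Over the sequence the apex is depressed and rebounds
    (air-puff applanation and recovery), following a raised-sine temporal
    profile.  Additive Gaussian noise and spurious bright blobs emulate the
    acquisition artifacts that defeat plain thresholding/edge baselines.
    """

    height: int = 150
    width: int = 576
    n_frames: int = 139
    band_thickness: int = 21
    apex_depression_max: float = 25.0
    noise_sigma: float = 0.05
    n_blob_artifacts: int = 5
    blob_intensity: float = 0.85
    seed: int = 0
    # geometry details (fractions of frame size); fixed defaults give a band
    # whose shape factor sits near the corneal prior C = 10 at 576x150
    apex_row_frac: float = 0.18
    edge_sag_frac: float = 0.30
    band_level: float = 0.85
    background_level: float = 0.08

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.n_frames) < 1:
            raise ConfigurationError("height, width and n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.band_thickness < 1:
            raise ConfigurationError("band_thickness must be >= 1")
        if self.apex_depression_max >= self.height - self.band_thickness:
            raise ConfigurationError(
                "apex_depression_max must be < height - band_thickness"
            )
        # the lowest band row over the whole sequence must stay inside the frame
        lowest = (
            self.apex_row_frac * self.height
            + self.edge_sag_frac * self.height
            + self.apex_depression_max
            + self.band_thickness
        )
        if lowest > self.height:
            raise ConfigurationError(
                f"band leaves the frame (lowest row {lowest:.1f} > height "
                f"{self.height}); reduce band_thickness or apex_depression_max"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SlicConfig:
    """SLIC pre-grouping parameters.

    ``n_superpixels`` is chosen so superpixels are much smaller than the
    corneal band thickness (grid spacing ~15 px at 576x150); ``compactness``
    is the method's m = 10.
    """

    n_superpixels: int = 400
    compactness: float = 10.0
    n_iter: int = 10

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise ConfigurationError("n_superpixels must be >= 2")
        if self.compactness <= 0:
            raise ConfigurationError("compactness must be > 0")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Per-frame unsupervised training parameters.

    ``alpha`` weights the shape-factor loss |Fs - C| added to the pixelwise
    cross-entropy; ``shape_target`` is the cornea-specific shape-factor
    constant C.  Training stops early once the total loss first drops below
    ``loss_stop_threshold`` or the number of distinct labels falls below
    ``min_labels``.
    """

    alpha: float = 0.1
    shape_target: float = 10.0
    lr: float = 0.1
    momentum: float = 0.9
    max_epochs_first_frame: int = 100
    max_epochs_warm: int = 30
    loss_stop_threshold: float = 0.1
    min_labels: int = 2
    seed: int = 0
    activation: str = "relu"
    shape_factor_gradient: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if self.loss_stop_threshold <= 0:
            raise ConfigurationError("loss_stop_threshold must be > 0")
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if self.min_labels < 1:
            raise ConfigurationError("min_labels must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(
                f"activation must be one of {ACTIVATIONS}, got {self.activation!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)
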