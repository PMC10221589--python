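"""Three-channel vessel image for the SL/EBL classifier.

The substernal-longitudinal (SL) and extrahepatic-bile-duct (EBL) views
show similar organ layouts, so they are separated by vessel appearance.
The vessel segmentation model (two classes: background and vessel) supplies
pre-activation mask predictions P; a ReLU — rather than a sigmoid — keeps
low-confidence positive responses while discarding negatives, so faint
vessels the hard segmentation missed still contribute signal.  The
classifier input is the H x W x 3 stack

    channel 0: original intensities inside the segmented vessel area, zero
               elsewhere;
    channel 1: ReLU'd background mask prediction;
    channel 2: ReLU'd vessel mask prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from PIL import Image
from skimage.transform import resize

from .segmentation_io import ValidationError
from .geometry import ConfigurationError


@dataclass(frozen=True)
class ThreeChannelImage:
    """The (vessel-masked intensity, background prediction, vessel
    prediction) raster, shape (H, W, 3)."""

    raster: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.raster, dtype=float)
        if r.ndim != 3 or r.shape[2] != 3:
            raise ValidationError(f"raster must be (H, W, 3), got {r.shape}")
        if (r[..., 1:] < 0).any():
            raise ValidationError("mask-prediction channels must be non-negative")
        object.__setattr__(self, "raster", r)

    @property
    def shape(self) -> tuple:
        return self.raster.shape


def relu_mask_predictions(mask_logits: np.ndarray) -> np.ndarray:
    """Elementwise max(P, 0)."""
    return np.maximum(np.asarray(mask_logits, dtype=float), 0.0)


def build_three_channel_image(
    image: np.ndarray, class_map: np.ndarray, relu_logits: np.ndarray
) -> ThreeChannelImage:
    """Assemble the SL/EBL classifier input from vessel-model outputs.

    ``relu_logits`` must be the (2, H, W) ReLU'd mask predictions of a
    two-class (background, vessel) model; ``class_map`` is its hard
    segmentation.  Intensities are carried through unmodified.
    """
    img = np.asarray(image, dtype=float)
    cm = np.asarray(class_map)
    rl = np.asarray(relu_logits, dtype=float)
    if rl.ndim != 3 or rl.shape[0] != 2:
        raise ConfigurationError(
            f"vessel model must have N=2 channels (background, vessel), got shape {rl.shape}"
        )
    if img.shape != cm.shape or rl.shape[1:] != img.shape:
        raise ValidationError(
            f"shape mismatch: image {img.shape}, class_map {cm.shape}, logits {rl.shape}"
        )
    if (rl < 0).any():
        raise ValidationError("relu_logits contains negative values; apply relu_mask_predictions first")
    vessel_masked = np.where(cm == 1, img, 0.0)
    return ThreeChannelImage(np.stack([vessel_masked, rl[0], rl[1]], axis=-1))


def preprocess_for_classifier(img: ThreeChannelImage, side: int = 224) -> np.ndarray:
    """Bilinear-resize to side x side and min-max scale each channel to
    [0, 1]; a constant channel maps to all zeros."""
    if side < 8:
        raise ValidationError(f"side must be >= 8, got {side}")
    r = img.raster
    if r.shape[:2] != (side, side):
        r = resize(r, (side, side, 3), order=1, anti_aliasing=False, preserve_range=True)
    out = np.empty_like(r)
    for c in range(3):
        ch = r[..., c]
        lo, hi = ch.min(), ch.max()
        out[..., c] = 0.0 if hi == lo else (ch - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------
# export
# ---------------------------------------------------------------------


def export_png(img: ThreeChannelImage, path) -> Path:
    """Export as RGB PNG for visual inspection.

    Display-only and lossy: each channel is independently scaled to 0-255
    and clipped to 8 bits.  Use :func:`export_hdf5` for pipeline use.
    """
    r = img.raster
    out = np.zeros(r.shape, dtype=np.uint8)
    for c in range(3):
        ch = r[..., c]
        lo, hi = ch.min(), ch.max()
        if hi > lo:
            out[..., c] = np.clip((ch - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="RGB").save(path)
    return Path(path)


def export_hdf5(img: ThreeChannelImage, path) -> Path:
    """Lossless export (little-endian float32)."""
    with h5py.File(path, "w", libver="earliest") as f:
        f.create_dataset("raster", data=img.raster.astype("<f4"), track_times=False)
    return Path(path)


def import_hdf5(path) -> ThreeChannelImage:
    with h5py.File(path, "r") as f:
        return ThreeChannelImage(f["raster"][()])
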