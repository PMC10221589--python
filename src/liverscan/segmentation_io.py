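"""Segmentation-artifact data model and disk I/O.

A segmentation backend (a MaskFormer-style network in production, the
built-in synthetic generator on a desk) emits, for every ultrasound frame,
a bundle of tensors: the grayscale image, a per-pixel class-label map, the
pre-activation per-class mask logits, the transformer-decoder per-segment
query embeddings, the encoder/FPN feature map and the per-query class
scores.  This module defines that bundle (:class:`SegmentationArtifact`),
validates it, converts soft outputs into hard per-class binary masks, and
round-trips bundles through a single HDF5 file per image.

Conventions used throughout the package:

* background is class index ``0``; organs/vessels are ``1 .. N-1``;
* pixel coordinates are 0-based with ``x`` = column and ``y`` = row,
  origin at the top-left; rasters are row-major;
* argmax ties break toward the lowest class index;
* arrays are serialized as little-endian 32-bit floats (images as uint8,
  class maps as int32) so fixtures are byte-reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from PIL import Image


class ValidationError(ValueError):
    """An artifact or raster violates a structural invariant."""


class ScanLocation(str, enum.Enum):
    """The 11 standardized liver ultrasound scan locations.

    Each code names a probe posture / view: substernal longitudinal (SL),
    substernal transverse (ST), right subcostal portal vein (RSPV), right
    subcostal right-liver transverse (RSLT), liver dome (LD), right
    subcostal hepatic vein (RSHV), gallbladder longitudinal (GBL),
    extrahepatic bile duct longitudinal (EBL), right intercostal oblique
    anterior/posterior (RIA/RIP) and liver-kidney (LK).
    """

    SL = "SL"
    ST = "ST"
    RSPV = "RSPV"
    RSLT = "RSLT"
    LD = "LD"
    RSHV = "RSHV"
    GBL = "GBL"
    EBL = "EBL"
    RIA = "RIA"
    RIP = "RIP"
    LK = "LK"


#: Canonical ordering of the 11 codes (declaration order).
ALL_LOCATIONS: tuple[ScanLocation, ...] = tuple(ScanLocation)


@dataclass(frozen=True)
class BinaryMask:
    """A set of foreground pixels on an H x W raster.

    ``pixels`` is a frozenset of ``(x, y)`` integer coordinates,
    0-based, ``x`` = column, ``y`` = row.
    """

    pixels: frozenset
    height: int
    width: int

    def __post_init__(self) -> None:
        for x, y in self.pixels:
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValidationError(
                    f"pixel ({x}, {y}) outside raster [0,{self.width})x[0,{self.height})"
                )

    def __len__(self) -> int:
        return len(self.pixels)

    def to_array(self) -> np.ndarray:
        """Render as a boolean H x W array."""
        arr = np.zeros((self.height, self.width), dtype=bool)
        for x, y in self.pixels:
            arr[y, x] = True
        return arr

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BinaryMask":
        ys, xs = np.nonzero(np.asarray(arr))
        h, w = arr.shape
        return cls(frozenset(zip(xs.tolist(), ys.tolist())), height=h, width=w)


# Dataset names inside an artifact bundle; order fixes the byte layout.
_BUNDLE_DATASETS = (
    "image",
    "class_map",
    "mask_logits",
    "query_embeddings",
    "feature_map",
    "class_scores",
)
_OPTIONAL_DATASETS = ("mask_logits", "query_embeddings", "feature_map", "class_scores")


@dataclass
class SegmentationArtifact:
    """Everything a segmentation backend reports for one image.

    Parameters
    ----------
    image
        Grayscale intensity raster, shape ``(H, W)``, values in 0-255.
    class_map
        Integer label raster, shape ``(H, W)``; 0 is background.
    n_classes
        Number of classes N including background.
    mask_logits
        Pre-activation per-class mask predictions, shape ``(N, H, W)``,
        or ``None`` when the backend did not expose them.
    query_embeddings
        Per-segment (query) embeddings, shape ``(C_Q, N)`` — one column
        per class/query, or ``None``.
    feature_map
        Encoder/FPN output, shape ``(C_F, H_F, W_F)``, or ``None``.
    class_scores
        Per-query class scores, shape ``(N, N+1)``; raw scores, whether
        these are logits or probabilities is left to consumers.
    subject_id
        Opaque subject identifier used for subject-wise splitting.
    label
        Ground-truth :class:`ScanLocation`, or ``None`` when unknown.
    """

    image: np.ndarray
    class_map: np.ndarray
    n_classes: int
    mask_logits: Optional[np.ndarray] = None
    query_embeddings: Optional[np.ndarray] = None
    feature_map: Optional[np.ndarray] = None
    class_scores: Optional[np.ndarray] = None
    subject_id: str = ""
    label: Optional[ScanLocation] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.class_map = np.asarray(self.class_map)
        # tensors live in the declared storage dtype (little-endian f32),
        # so write/read round-trips are exact
        for name in _OPTIONAL_DATASETS:
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype="<f4"))
        self.validate()

    # -- validation --------------------------------------------------

    def validate(self) -> None:
        if self.image.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {self.image.shape}")
        if self.class_map.shape != self.image.shape:
            raise ValidationError(
                f"class_map shape {self.class_map.shape} does not match "
                f"image shape {self.image.shape}"
            )
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2 (background + foreground)")
        cm = self.class_map
        if cm.size and (cm.min() < 0 or cm.max() >= self.n_classes):
            raise ValidationError(
                f"class_map values must lie in [0, {self.n_classes - 1}], "
                f"found range [{cm.min()}, {cm.max()}]"
            )
        if self.mask_logits is not None:
            ml = np.asarray(self.mask_logits)
            if ml.shape != (self.n_classes,) + self.image.shape:
                raise ValidationError(
                    f"mask_logits shape {ml.shape} incompatible with "
                    f"(N={self.n_classes}, H, W)={(self.n_classes,) + self.image.shape}"
                )
        if self.query_embeddings is not None:
            qe = np.asarray(self.query_embeddings)
            if qe.ndim != 2 or qe.shape[1] != self.n_classes:
                raise ValidationError(
                    f"query_embeddings must have shape (C_Q, N={self.n_classes}), "
                    f"got {qe.shape}"
                )
        if self.class_scores is not None:
            cs = np.asarray(self.class_scores)
            if cs.shape != (self.n_classes, self.n_classes + 1):
                raise ValidationError(
                    f"class_scores must have shape (N, N+1)="
                    f"{(self.n_classes, self.n_classes + 1)}, got {cs.shape}"
                )
        if self.feature_map is not None and np.asarray(self.feature_map).ndim != 3:
            raise ValidationError("feature_map must be a 3-D (C_F, H_F, W_F) tensor")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def with_label(self, label: Optional[ScanLocation]) -> "SegmentationArtifact":
        return replace(self, label=label)

    def equals(self, other: "SegmentationArtifact") -> bool:
        """Exact equality of all tensors, metadata and absence flags."""
        if (self.n_classes, self.subject_id, self.label) != (
            other.n_classes,
            other.subject_id,
            other.label,
        ):
            return False
        for name in _BUNDLE_DATASETS:
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(np.asarray(a), np.asarray(b)):
                return False
        return True


# ---------------------------------------------------------------------
# soft output -> hard masks
# ---------------------------------------------------------------------


def class_map_from_logits(mask_logits: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the class dimension of an (N, H, W) tensor.

    Ties break toward the lowest class index (``np.argmax`` semantics,
    asserted by the test-suite oracle).
    """
    ml = np.asarray(mask_logits)
    if ml.size == 0 or ml.ndim != 3:
        raise ValidationError(f"mask_logits must be a non-empty (N,H,W) tensor, got shape {ml.shape}")
    if ml.shape[0] < 2:
        raise ValidationError("need at least 2 channels (background + 1 class)")
    return np.argmax(ml, axis=0).astype(np.int32)


def binary_masks(class_map: np.ndarray, n_classes: int) -> list[BinaryMask]:
    """Split an integer label raster into N-1 per-class binary masks.

    Mask ``i-1`` in the returned list holds exactly the pixels labeled
    ``i`` for ``i = 1 .. N-1``; the background class produces no mask.
    """
    cm = np.asarray(class_map)
    if cm.size and cm.max() >= n_classes:
        raise ValidationError(
            f"label {int(cm.max())} out of range for n_classes={n_classes}"
        )
    h, w = cm.shape
    out = []
    for i in range(1, n_classes):
        ys, xs = np.nonzero(cm == i)
        out.append(BinaryMask(frozenset(zip(xs.tolist(), ys.tolist())), height=h, width=w))
    return out


# ---------------------------------------------------------------------
# HDF5 bundle I/O
# ---------------------------------------------------------------------


def write_artifact(artifact: SegmentationArtifact, path) -> Path:
    """Write one artifact to a single self-describing HDF5 bundle.

    The byte layout is deterministic for a fixed artifact: datasets are
    created in a fixed order with timestamp tracking disabled, floats as
    little-endian float32.
    """
    artifact.validate()
    path = Path(path)
    try:
        f = h5py.File(path, "w", libver="earliest")
    except OSError as exc:  # unwritable path
        raise IOError(f"cannot write artifact bundle to {path}: {exc}") from exc
    with f:
        def put(name: str, arr, dtype) -> None:
            f.create_dataset(name, data=np.asarray(arr).astype(dtype), track_times=False)

        put("image", artifact.image, "<u1")
        put("class_map", artifact.class_map, "<i4")
        for name in _OPTIONAL_DATASETS:
            arr = getattr(artifact, name)
            if arr is not None:
                put(name, arr, "<f4")
        f.attrs["n_classes"] = np.int32(artifact.n_classes)
        f.attrs["subject_id"] = artifact.subject_id
        f.attrs["label"] = artifact.label.value if artifact.label is not None else ""
    return path


def read_artifact(path) -> SegmentationArtifact:
    """Read a bundle written by :func:`write_artifact`.

    Tensors absent from the bundle come back as ``None``; the returned
    artifact is re-validated.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"artifact bundle not found: {path}")
    with h5py.File(path, "r") as f:
        kwargs = {}
        for name in _OPTIONAL_DATASETS:
            kwargs[name] = f[name][()] if name in f else None
        label_str = f.attrs.get("label", "")
        if isinstance(label_str, bytes):
            label_str = label_str.decode()
        return SegmentationArtifact(
            image=f["image"][()],
            class_map=f["class_map"][()],
            n_classes=int(f.attrs["n_classes"]),
            subject_id=str(f.attrs.get("subject_id", "")),
            label=ScanLocation(label_str) if label_str else None,
            **kwargs,
        )


# ---------------------------------------------------------------------
# PNG import/export and dataset manifests
# ---------------------------------------------------------------------

# A fixed 256-entry palette for label PNGs: background black, classes in
# saturated distinguishable colors (deterministic).
def _label_palette() -> list[int]:
    rng = np.random.default_rng(2023)
    pal = rng.integers(32, 256, size=(256, 3))
    pal[0] = 0
    return [int(v) for v in pal.ravel()]


def export_image_png(image: np.ndarray, path) -> Path:
    """Export a grayscale intensity raster as 8-bit grayscale PNG."""
    Image.fromarray(np.asarray(image).astype(np.uint8), mode="L").save(path)
    return Path(path)


def import_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def export_class_map_png(class_map: np.ndarray, path) -> Path:
    """Export an integer label raster as a paletted 8-bit PNG."""
    cm = np.asarray(class_map)
    if cm.max(initial=0) > 255:
        raise ValidationError("paletted PNG supports at most 256 classes")
    img = Image.fromarray(cm.astype(np.uint8), mode="P")
    img.putpalette(_label_palette())
    img.save(path)
    return Path(path)


def import_class_map_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise ValidationError(f"expected paletted label PNG, got mode {img.mode}")
    return np.asarray(img).astype(np.int32)


def write_manifest(rows: Iterable[tuple[str, str, Optional[str]]], path) -> Path:
    """Write a dataset manifest CSV with columns path,subject_id,label."""
    df = pd.DataFrame(list(rows), columns=["path", "subject_id", "label"])
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"path": str, "subject_id": str, "label": str})
    missing = {"path", "subject_id", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return df
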