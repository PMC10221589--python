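"""Global long-term features from segmentation outputs.

Three feature families feed the scan-location classifiers:

1. *Image features* ``G``: global average pooling of the encoder/FPN
   feature map — ``G_i`` is the spatial mean of channel ``i``.
2. *Per-segment (query) embeddings* ``Q`` and per-query *class scores*,
   flattened as-is.
3. *Geometric features* ``V``: an ``(N-1) x 10`` matrix with one row per
   non-background class, ``V_i = [T_i, L_x, L_y, S_i, λ1, λ2, v1x, v1y,
   v2x, v2y]`` — detection tag, centroid, area fraction, and the
   eigenstructure of the 2x2 covariance matrix of the class's pixel
   coordinates (a shape-PCA morphology descriptor).  Rows for undetected
   classes are all zeros.

`assemble_feature_vector` concatenates any subset of those segments into
one flat classifier input with a recorded layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import json
import numpy as np
import pandas as pd

from .segmentation_io import (
    BinaryMask,
    SegmentationArtifact,
    ValidationError,
    binary_masks,
)


class DegenerateMaskError(ValueError):
    """Centroid/morphology requested for an empty mask."""


class ConfigurationError(ValueError):
    """A requested feature segment is absent from the artifact."""


#: Column layout of one geometric-feature row.
GEOMETRIC_COLUMNS = ("tag", "cx", "cy", "size", "lam1", "lam2", "v1x", "v1y", "v2x", "v2y")

#: Feature-vector segment names in concatenation order.
FEATURE_PARTS = ("gap", "queries", "class_scores", "geometric")


@dataclass(frozen=True)
class GeometricFeatures:
    """The (N-1) x 10 per-class geometric descriptor matrix V."""

    matrix: np.ndarray  # shape (N-1, 10)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 10:
            raise ValidationError(f"geometric matrix must be (N-1, 10), got {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_classes(self) -> int:
        """N, including background."""
        return self.matrix.shape[0] + 1


@dataclass(frozen=True)
class FeatureVector:
    """A flat classifier input with its segment layout.

    ``offsets`` maps each included part name to its ``(start, stop)``
    slice in ``values``.
    """

    values: np.ndarray
    offsets: dict

    def __post_init__(self) -> None:
        total = sum(stop - start for start, stop in self.offsets.values())
        if total != self.values.shape[0]:
            raise ValidationError(
                f"segment lengths sum to {total} but vector has {self.values.shape[0]} entries"
            )

    def segment(self, part: str) -> np.ndarray:
        start, stop = self.offsets[part]
        return self.values[start:stop]


# ---------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------


def global_average_pool(feature_map: np.ndarray) -> np.ndarray:
    """Spatial mean per channel of a (C_F, H_F, W_F) tensor."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 3 or fm.shape[1] < 1 or fm.shape[2] < 1:
        raise ValidationError(
            f"feature map must be (C_F, H_F>=1, W_F>=1), got shape {fm.shape}"
        )
    return fm.mean(axis=(1, 2))


def class_tag(mask: BinaryMask) -> int:
    """1 iff the class is detected (mask non-empty), else 0."""
    return int(len(mask) > 0)


def centroid(mask: BinaryMask) -> tuple[float, float]:
    """Mean (x, y) of member pixels, in raw pixel units."""
    if len(mask) == 0:
        raise DegenerateMaskError("centroid of an empty mask is undefined")
    xs = np.fromiter((p[0] for p in mask.pixels), dtype=float, count=len(mask))
    ys = np.fromiter((p[1] for p in mask.pixels), dtype=float, count=len(mask))
    return float(xs.mean()), float(ys.mean())


def size_fraction(mask: BinaryMask) -> float:
    """|C_i| / (H * W); 0 for an empty mask."""
    area = mask.height * mask.width
    if area <= 0:
        raise ValidationError("raster must have positive area")
    return len(mask) / area


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude component is positive;
    on a magnitude tie, the first component is positive."""
    idx = int(np.argmax(np.abs(v)))  # argmax breaks ties toward index 0
    if v[idx] < 0:
        return -v
    return v


def morphology(mask: BinaryMask) -> np.ndarray:
    """Eigenstructure of the pixel-coordinate covariance matrix.

    Returns ``[λ1, λ2, v1x, v1y, v2x, v2y]`` with λ1 >= λ2 >= 0 (population
    1/n normalization, pixel² units) and unit eigenvectors.  Degenerate
    cases — a single pixel, or a repeated eigenvalue — return the canonical
    basis (1,0), (0,1).
    """
    if len(mask) == 0:
        raise DegenerateMaskError("morphology of an empty mask is undefined")
    coords = np.array(sorted(mask.pixels), dtype=float)  # (n, 2) columns x, y
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(mask)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam1, lam2 = float(evals[1]), float(evals[0])
    lam1, lam2 = max(lam1, 0.0), max(lam2, 0.0)
    if np.isclose(lam1, lam2):
        v1, v2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    else:
        v1 = _fix_sign(evecs[:, 1].copy())
        v2 = _fix_sign(evecs[:, 0].copy())
    return np.array([lam1, lam2, v1[0], v1[1], v2[0], v2[1]])


def geometric_feature_matrix(
    class_map: np.ndarray,
    n_classes: int,
    *,
    normalize: bool = False,
) -> GeometricFeatures:
    """Assemble V from the four component operations.

    Rows for undetected classes are all zeros.  With ``normalize=True``
    the centroid is divided by (W, H) and the eigenvalues by W*H
    (dimensionless variant; default off, matching the raw-pixel-unit
    formulation).
    """
    masks = binary_masks(class_map, n_classes)
    h, w = np.asarray(class_map).shape
    rows = np.zeros((n_classes - 1, 10))
    for i, mask in enumerate(masks):
        if class_tag(mask) == 0:
            continue
        cx, cy = centroid(mask)
        morph = morphology(mask)
        if normalize:
            cx, cy = cx / w, cy / h
            morph = morph.copy()
            morph[:2] /= h * w
        rows[i] = [1.0, cx, cy, size_fraction(mask), *morph]
    return GeometricFeatures(rows)


# ---------------------------------------------------------------------
# feature-vector assembly
# ---------------------------------------------------------------------


def assemble_feature_vector(
    artifact: SegmentationArtifact,
    parts: Sequence[str] = FEATURE_PARTS,
    *,
    geometric_classes: Optional[Sequence[int]] = None,
    normalize_geometry: bool = False,
) -> FeatureVector:
    """Concatenate the requested feature segments in fixed order.

    Parameters
    ----------
    parts
        Subset of ``("gap", "queries", "class_scores", "geometric")``;
        segments always appear in this canonical order regardless of the
        order given.
    geometric_classes
        Optional restriction of the geometric matrix to these class
        indices (1-based, background excluded); rows for other classes
        are dropped.  Used by hierarchy stages that consume liver-only
        geometry.
    """
    unknown = set(parts) - set(FEATURE_PARTS)
    if unknown:
        raise ConfigurationError(f"unknown feature parts: {sorted(unknown)}")
    segments: list[tuple[str, np.ndarray]] = []
    for part in FEATURE_PARTS:
        if part not in parts:
            continue
        if part == "gap":
            if artifact.feature_map is None:
                raise ConfigurationError("part 'gap' requested but artifact has no feature_map")
            seg = global_average_pool(artifact.feature_map)
        elif part == "queries":
            if artifact.query_embeddings is None:
                raise ConfigurationError(
                    "part 'queries' requested but artifact has no query_embeddings"
                )
            seg = np.asarray(artifact.query_embeddings, dtype=float).ravel()
        elif part == "class_scores":
            if artifact.class_scores is None:
                raise ConfigurationError(
                    "part 'class_scores' requested but artifact has no class_scores"
                )
            seg = np.asarray(artifact.class_scores, dtype=float).ravel()
        else:  # geometric
            gf = geometric_feature_matrix(
                artifact.class_map, artifact.n_classes, normalize=normalize_geometry
            )
            m = gf.matrix
            if geometric_classes is not None:
                idx = [c - 1 for c in geometric_classes]
                m = m[idx]
            seg = m.ravel()
        segments.append((part, seg))

    offsets = {}
    pos = 0
    for name, seg in segments:
        offsets[name] = (pos, pos + seg.shape[0])
        pos += seg.shape[0]
    values = np.concatenate([seg for _, seg in segments]) if segments else np.zeros(0)
    return FeatureVector(values=values, offsets=offsets)


# ---------------------------------------------------------------------
# batch export
# ---------------------------------------------------------------------


def export_features_csv(
    artifacts: Iterable[SegmentationArtifact],
    path,
    parts: Sequence[str] = FEATURE_PARTS,
) -> Path:
    """One row per image, columns named ``<segment>_<index>``; a JSON
    sidecar ``<path>.meta.json`` records the layout."""
    path = Path(path)
    rows, meta = [], None
    for art in artifacts:
        fv = assemble_feature_vector(art, parts)
        if meta is None:
            meta = {
                "parts": list(fv.offsets),
                "offsets": {k: list(v) for k, v in fv.offsets.items()},
                "n_classes": art.n_classes,
                "c_f": None if art.feature_map is None else int(np.asarray(art.feature_map).shape[0]),
                "c_q": None
                if art.query_embeddings is None
                else int(np.asarray(art.query_embeddings).shape[0]),
            }
        row = {"subject_id": art.subject_id, "label": art.label.value if art.label else ""}
        for part, (start, stop) in fv.offsets.items():
            for j, v in enumerate(fv.values[start:stop]):
                row[f"{part}_{j}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if meta is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
    return path
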