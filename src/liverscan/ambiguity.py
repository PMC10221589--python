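"""Ambiguous-sample handling for the ST/RSPV/RSHV group.

The three right-lobe views share organ layout and differ mainly in vessel
morphology; probe motion makes many frames genuinely ambiguous between
them.  The strategy:

1. train a triplet-loss encoder on *clear* samples (those the initial
   group classifier gets right), producing 64-d embeddings in which the
   three classes separate;
2. project the clear embeddings to 2-D with t-SNE, overlay a uniform
   10 x 10 grid on the bounding box of the projection, and sample one
   clear point uniformly from every occupied cell — these become the
   *reference points*, kept with their 64-d embeddings and labels;
3. classify queries by k-nearest-neighbor voting (k = 3, Euclidean
   distance in the 64-d space) against the reference points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from ._nn import TripletConfig, TripletEncoder, triplet_loss  # noqa: F401 (re-export)
from .segmentation_io import ScanLocation, ValidationError
from .geometry import ConfigurationError

logger = logging.getLogger(__name__)

#: Spec'd encoder settings: 3 layers, 64-d output, margin 1.
TripletEncoderConfig = TripletConfig

DEFAULT_GRID = (10, 10)
DEFAULT_PERPLEXITY = 30.0


@dataclass(frozen=True)
class ReferenceEntry:
    embedding: np.ndarray  # 64-d
    label: ScanLocation
    tsne_xy: tuple[float, float]
    cell: tuple[int, int]  # (row, col)


@dataclass
class ReferenceSet:
    """Clear-data prototypes, one per occupied t-SNE grid cell."""

    entries: list[ReferenceEntry]
    grid: tuple[int, int]
    bounds: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    seed: int

    def __post_init__(self) -> None:
        cells = [e.cell for e in self.entries]
        if len(cells) != len(set(cells)):
            raise ValidationError("reference set has multiple entries in one grid cell")
        if len(self.entries) > self.grid[0] * self.grid[1]:
            raise ValidationError("more references than grid cells")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def embeddings(self) -> np.ndarray:
        return np.stack([e.embedding for e in self.entries])

    @property
    def labels(self) -> list[ScanLocation]:
        return [e.label for e in self.entries]


def train_triplet_encoder(
    features: np.ndarray,
    labels: Sequence,
    config: Optional[TripletEncoderConfig] = None,
    groups=None,
) -> TripletEncoder:
    """Fit the 3-layer triplet encoder on clear-data feature vectors.

    Deterministic given ``config.seed``; requires >= 2 classes with >= 2
    samples each (otherwise no triplet can be mined for some class).
    ``groups`` (subject ids), when given, select a subject-held-out
    validation split for early stopping.
    """
    return TripletEncoder(config or TripletEncoderConfig()).fit(
        np.asarray(features, dtype=float),
        np.asarray([str(l) for l in labels]),
        groups=groups,
    )


def _grid_cell(
    xy: np.ndarray, bounds: tuple, rows: int, cols: int
) -> tuple[int, int]:
    """Cell of a 2-D point; cells are half-open on the right/top edge
    except the last row/column, which is closed."""
    xmin, xmax, ymin, ymax = bounds
    wx = (xmax - xmin) / cols if xmax > xmin else 1.0
    wy = (ymax - ymin) / rows if ymax > ymin else 1.0
    col = min(int((xy[0] - xmin) / wx), cols - 1)
    row = min(int((xy[1] - ymin) / wy), rows - 1)
    return row, col


def tsne_embed(embeddings: np.ndarray, seed: int, perplexity: float = DEFAULT_PERPLEXITY) -> np.ndarray:
    """2-D t-SNE of the encoder outputs (Euclidean, fixed seed).

    When there are too few points for the requested perplexity, it is
    reduced (with a logged warning) rather than failing.
    """
    emb = np.asarray(embeddings, dtype=float)
    n = len(emb)
    if n == 0:
        raise ValidationError("need at least one embedding")
    if n <= 2:
        # TSNE cannot run; a degenerate layout along one axis is enough
        return np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    if np.allclose(emb, emb[0]):
        # identical points: t-SNE diverges on zero variance; any common
        # layout point is equivalent (all land in one grid cell)
        return np.zeros((n, 2))
    max_perp = (n - 1) / 3.0
    if perplexity >= max_perp:
        perplexity = max(1.0, max_perp * 0.9)
        logger.warning("too few points for requested perplexity; reduced to %.2f", perplexity)
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        metric="euclidean",
    )
    return ts.fit_transform(emb)


def select_reference_points(
    embeddings: np.ndarray,
    labels: Sequence[ScanLocation],
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    seed: int = 0,
    perplexity: float = DEFAULT_PERPLEXITY,
) -> ReferenceSet:
    """Build the reference set: t-SNE, uniform grid, one sample per
    occupied cell (uniform over the cell's members)."""
    emb = np.asarray(embeddings, dtype=float)
    labels = list(labels)
    if len(emb) == 0:
        raise ValidationError("need at least one embedding")
    if len(labels) != len(emb):
        raise ValidationError("labels and embeddings length mismatch")
    xy = tsne_embed(emb, seed=seed, perplexity=perplexity)
    bounds = (
        float(xy[:, 0].min()),
        float(xy[:, 0].max()),
        float(xy[:, 1].min()),
        float(xy[:, 1].max()),
    )
    cells: dict[tuple[int, int], list[int]] = {}
    for i, point in enumerate(xy):
        cells.setdefault(_grid_cell(point, bounds, grid_rows, grid_cols), []).append(i)
    rng = np.random.default_rng(seed)
    entries = []
    for cell in sorted(cells):
        members = cells[cell]
        pick = members[int(rng.integers(len(members)))]
        entries.append(
            ReferenceEntry(
                embedding=emb[pick].copy(),
                label=ScanLocation(labels[pick]),
                tsne_xy=(float(xy[pick, 0]), float(xy[pick, 1])),
                cell=cell,
            )
        )
    return ReferenceSet(entries=entries, grid=(grid_rows, grid_cols), bounds=bounds, seed=seed)


def knn_classify(query: np.ndarray, refs: ReferenceSet, k: int = 3) -> ScanLocation:
    """Majority vote among the k Euclidean-nearest reference points.

    Vote ties break toward the single nearest neighbor's label; distance
    ties break by reference insertion order (stable sort).
    """
    if len(refs) < k or k < 1:
        raise ConfigurationError(f"need 1 <= k <= |refs|; got k={k}, |refs|={len(refs)}")
    q = np.asarray(query, dtype=float)
    dists = np.linalg.norm(refs.embeddings - q[None, :], axis=1)
    order = np.argsort(dists, kind="stable")[:k]
    votes: dict[ScanLocation, int] = {}
    labels = refs.labels
    for i in order:
        votes[labels[i]] = votes.get(labels[i], 0) + 1
    best = max(votes.values())
    winners = [lab for lab, c in votes.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    return labels[order[0]]


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------


def write_reference_set(refs: ReferenceSet, path) -> Path:
    with h5py.File(path, "w", libver="earliest") as f:
        f.create_dataset("embeddings", data=refs.embeddings.astype("<f4"), track_times=False)
        f.create_dataset(
            "labels",
            data=np.array([e.label.value for e in refs.entries], dtype="S8"),
            track_times=False,
        )
        f.create_dataset(
            "tsne_xy",
            data=np.array([e.tsne_xy for e in refs.entries], dtype="<f4"),
            track_times=False,
        )
        f.create_dataset(
            "cells", data=np.array([e.cell for e in refs.entries], dtype="<i4"), track_times=False
        )
        f.attrs["grid"] = np.array(refs.grid, dtype=np.int32)
        f.attrs["bounds"] = np.array(refs.bounds, dtype=np.float64)
        f.attrs["seed"] = np.int64(refs.seed)
    return Path(path)


def read_reference_set(path) -> ReferenceSet:
    with h5py.File(path, "r") as f:
        emb = f["embeddings"][()]
        labels = [ScanLocation(s.decode()) for s in f["labels"][()]]
        xy = f["tsne_xy"][()]
        cells = f["cells"][()]
        entries = [
            ReferenceEntry(
                embedding=emb[i].astype(float),
                label=labels[i],
                tsne_xy=(float(xy[i, 0]), float(xy[i, 1])),
                cell=(int(cells[i, 0]), int(cells[i, 1])),
            )
            for i in range(len(labels))
        ]
        return ReferenceSet(
            entries=entries,
            grid=tuple(int(v) for v in f.attrs["grid"]),
            bounds=tuple(float(v) for v in f.attrs["bounds"]),
            seed=int(f.attrs["seed"]),
        )


def reference_set_summary(refs: ReferenceSet) -> pd.DataFrame:
    """Inspection table: one row per reference point."""
    return pd.DataFrame(
        {
            "label": [e.label.value for e in refs.entries],
            "row": [e.cell[0] for e in refs.entries],
            "col": [e.cell[1] for e in refs.entries],
            "tsne_x": [e.tsne_xy[0] for e in refs.entries],
            "tsne_y": [e.tsne_xy[1] for e in refs.entries],
        }
    )
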