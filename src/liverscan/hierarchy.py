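"""Hierarchical scan-location classification.

Routing (feed-forward, two levels):

1. *Level 1* — an MLP over organ-segmentation features maps each frame to
   one of 8 regions: the six unambiguous locations (RSLT, LD, GBL, RIA,
   RIP, LK) plus two groups of mutually confusable locations,
   {ST, RSPV, RSHV} (right lobe) and {SL, EBL} (longitudinal views).
   Organ information alone suffices at this level.
2. *Group 1* ({ST, RSPV, RSHV}) — an MLP over liver + vessel features
   (sub-step 1) partitions training data into clear/ambiguous; a triplet
   encoder trained on the clear samples plus reference-point KNN
   (sub-step 2) produces the final label.  At inference every group-1
   frame is classified by the KNN (sub-step 1 exists to define clear
   data); confidence-thresholded routing is available as an option.
3. *Group 2* ({SL, EBL}) — an image classifier on the three-channel
   vessel image (masked intensity, background prediction, vessel
   prediction).

A non-hierarchical ablation trains a single MLP on the concatenated
organ + vessel features over all 11 labels.

All classifiers share the optimization recipe: two fully connected
layers, cross-entropy, AdamW at learning rate 1e-4, early stopping with
patience 10 on validation loss.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ._nn import DataError, SoftmaxMLP, TrainConfig, TripletConfig, TripletEncoder
from .ambiguity import (
    ReferenceSet,
    knn_classify,
    read_reference_set,
    select_reference_points,
    train_triplet_encoder,
    write_reference_set,
)
from .geometry import FEATURE_PARTS, assemble_feature_vector
from .segmentation_io import ScanLocation, ValidationError
from .synthetic import SamplePair
from .vessel_image import (
    build_three_channel_image,
    preprocess_for_classifier,
    relu_mask_predictions,
)


class RoutingError(RuntimeError):
    """An artifact required by the routed branch is missing."""


class DegenerateReferenceError(DataError):
    """A group-1 label has no clear samples to build references from."""


class RegionGroup(str, enum.Enum):
    """The 8 level-1 classes: six locations plus two confusable groups."""

    GROUP_ST_RSPV_RSHV = "ST|RSPV|RSHV"
    GROUP_SL_EBL = "SL|EBL"
    RSLT = "RSLT"
    LD = "LD"
    GBL = "GBL"
    RIA = "RIA"
    RIP = "RIP"
    LK = "LK"


GROUP1_LABELS = (ScanLocation.ST, ScanLocation.RSPV, ScanLocation.RSHV)
GROUP2_LABELS = (ScanLocation.SL, ScanLocation.EBL)

#: Members of each level-1 class (the fibers of group_label).
GROUP_MEMBERS = {
    RegionGroup.GROUP_ST_RSPV_RSHV: set(GROUP1_LABELS),
    RegionGroup.GROUP_SL_EBL: set(GROUP2_LABELS),
    **{RegionGroup(l.value): {ScanLocation(l.value)} for l in
       (RegionGroup.RSLT, RegionGroup.LD, RegionGroup.GBL,
        RegionGroup.RIA, RegionGroup.RIP, RegionGroup.LK)},
}


def group_label(label: ScanLocation) -> RegionGroup:
    """The 11 -> 8 surjection onto level-1 classes."""
    if label in GROUP1_LABELS:
        return RegionGroup.GROUP_ST_RSPV_RSHV
    if label in GROUP2_LABELS:
        return RegionGroup.GROUP_SL_EBL
    return RegionGroup(label.value)


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------


@dataclass
class HierarchyConfig:
    """Stage hyperparameters and seeds.

    ``group1_organ_geometric_classes`` restricts the organ geometric rows
    fed to group-1 (default: liver only, class index 1); set to ``None``
    to keep all rows.  ``group1_routing`` selects whether every group-1
    frame goes through the KNN ("knn_all", default) or only frames the
    sub-step-1 classifier is unsure about ("confidence").
    """

    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    triplet: TripletConfig = field(default_factory=TripletConfig)
    level1_parts: tuple = FEATURE_PARTS
    group1_organ_parts: tuple = FEATURE_PARTS
    group1_organ_geometric_classes: Optional[tuple] = (1,)
    group1_vessel_parts: tuple = FEATURE_PARTS
    group1_routing: str = "knn_all"
    group1_confidence_threshold: float = 0.9
    knn_k: int = 3
    grid: tuple = (10, 10)
    tsne_perplexity: float = 30.0
    group2_side: int = 32  # desk-scale preprocessing resolution
    group2_pool: int = 16  # average-pooling stem factor (coarse 2x2 map + stats)
    group2_backbone: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def stage_train(self, offset: int) -> TrainConfig:
        return replace(self.train, seed=(self.seed + offset) % (2**31 - 1))


# ---------------------------------------------------------------------
# feature builders
# ---------------------------------------------------------------------


def level1_features(pair: SamplePair, config: HierarchyConfig) -> np.ndarray:
    """Organ-model features only (the level-1 contract)."""
    return assemble_feature_vector(pair.organ, config.level1_parts).values


def group1_features(pair: SamplePair, config: HierarchyConfig) -> np.ndarray:
    """Liver-restricted organ features concatenated with the full vessel
    feature vector."""
    if pair.vessel is None:
        raise RoutingError("group-1 branch requires a vessel artifact")
    organ_vec = assemble_feature_vector(
        pair.organ,
        config.group1_organ_parts,
        geometric_classes=config.group1_organ_geometric_classes,
    ).values
    vessel_vec = assemble_feature_vector(pair.vessel, config.group1_vessel_parts).values
    return np.concatenate([organ_vec, vessel_vec])


def non_hierarchical_features(pair: SamplePair, config: HierarchyConfig) -> np.ndarray:
    """Concatenated organ + vessel feature vectors (all parts)."""
    if pair.vessel is None:
        raise RoutingError("the non-hierarchical classifier requires a vessel artifact")
    return np.concatenate(
        [
            assemble_feature_vector(pair.organ, FEATURE_PARTS).values,
            assemble_feature_vector(pair.vessel, FEATURE_PARTS).values,
        ]
    )


def pooling_backbone(pool: int) -> Callable[[np.ndarray], np.ndarray]:
    """Desk-scale image feature extractor.

    Non-overlapping average pooling by ``pool`` (flattened), plus global
    photometric statistics per channel — mean, std, max, quartiles and
    occupancy of the non-zero (structure) pixels.  The statistics carry
    the echogenicity of the segmented vessel relative to the channel's
    dynamic range, which is subject-invariant where per-position layout
    features are not.  Any callable mapping an (side, side, 3) array to
    a 1-D vector can replace the whole backbone (e.g. a large pretrained
    CNN in a fidelity deployment).
    """

    def backbone(img: np.ndarray) -> np.ndarray:
        h, w, c = img.shape
        hp, wp = h // pool, w // pool
        pooled = img[: hp * pool, : wp * pool].reshape(hp, pool, wp, pool, c).mean(axis=(1, 3))
        stats = []
        for ch in range(c):
            vals = img[..., ch]
            nz = vals[vals > 0]
            if len(nz) == 0:
                nz = np.zeros(1)
            stats.extend(
                [
                    vals.mean(),
                    vals.std(),
                    vals.max(),
                    np.quantile(nz, 0.25),
                    np.quantile(nz, 0.5),
                    np.quantile(nz, 0.75),
                    nz.size / vals.size,
                ]
            )
        return np.concatenate([pooled.ravel(), stats])

    return backbone


def group2_image_features(pair: SamplePair, config: HierarchyConfig) -> np.ndarray:
    """Three-channel vessel image -> preprocessed raster -> backbone features."""
    if pair.vessel is None:
        raise RoutingError("group-2 branch requires a vessel artifact")
    if pair.vessel.mask_logits is None:
        raise RoutingError("group-2 branch requires vessel mask logits")
    relu = relu_mask_predictions(pair.vessel.mask_logits)
    img = build_three_channel_image(pair.vessel.image, pair.vessel.class_map, relu)
    pre = preprocess_for_classifier(img, side=config.group2_side)
    backbone = config.group2_backbone or pooling_backbone(config.group2_pool)
    return backbone(pre)


# ---------------------------------------------------------------------
# stage training
# ---------------------------------------------------------------------


def train_level1(samples: Sequence[SamplePair], config: HierarchyConfig) -> SoftmaxMLP:
    """Train the 8-region classifier on organ features."""
    groups = [group_label(s.label) for s in samples]
    missing = set(RegionGroup) - set(groups)
    if missing:
        raise DataError(f"level-1 training data lacks region groups: {sorted(g.name for g in missing)}")
    X = np.stack([level1_features(s, config) for s in samples])
    y = np.array([g.value for g in groups])
    subj = np.array([s.subject_id for s in samples])
    return SoftmaxMLP(config.stage_train(1)).fit(X, y, groups=subj)


@dataclass
class Group1Model:
    substep1: SoftmaxMLP
    encoder: TripletEncoder
    refs: ReferenceSet
    clear_fraction: float


def train_group1(samples: Sequence[SamplePair], config: HierarchyConfig) -> Group1Model:
    """Sub-step-1 MLP, clear/ambiguous partition, triplet encoder and
    reference set for the ST/RSPV/RSHV group."""
    labels = {s.label for s in samples}
    if set(GROUP1_LABELS) - labels:
        raise DataError(
            f"group-1 training data lacks labels: {sorted(l.value for l in set(GROUP1_LABELS) - labels)}"
        )
    X = np.stack([group1_features(s, config) for s in samples])
    y = np.array([s.label.value for s in samples])
    subj = np.array([s.subject_id for s in samples])
    substep1 = SoftmaxMLP(config.stage_train(2)).fit(X, y, groups=subj)
    # clear data = training samples sub-step 1 itself predicts correctly
    clear_mask = substep1.predict(X) == y
    clear_fraction = float(clear_mask.mean())
    clear_labels = set(y[clear_mask])
    empty = {l.value for l in GROUP1_LABELS} - clear_labels
    if empty:
        raise DegenerateReferenceError(f"no clear samples for labels: {sorted(empty)}")
    triplet_cfg = replace(config.triplet, seed=(config.seed + 3) % (2**31 - 1))
    encoder = train_triplet_encoder(
        X[clear_mask], y[clear_mask], triplet_cfg, groups=subj[clear_mask]
    )
    emb = encoder.transform(X[clear_mask])
    refs = select_reference_points(
        emb,
        [ScanLocation(v) for v in y[clear_mask]],
        grid_rows=config.grid[0],
        grid_cols=config.grid[1],
        seed=(config.seed + 4) % (2**31 - 1),
        perplexity=config.tsne_perplexity,
    )
    return Group1Model(substep1=substep1, encoder=encoder, refs=refs, clear_fraction=clear_fraction)


def train_group2(samples: Sequence[SamplePair], config: HierarchyConfig) -> SoftmaxMLP:
    """Train the SL/EBL image classifier on three-channel vessel images."""
    labels = {s.label for s in samples}
    if set(GROUP2_LABELS) - labels:
        raise DataError(
            f"group-2 training data lacks labels: {sorted(l.value for l in set(GROUP2_LABELS) - labels)}"
        )
    X = np.stack([group2_image_features(s, config) for s in samples])
    y = np.array([s.label.value for s in samples])
    subj = np.array([s.subject_id for s in samples])
    return SoftmaxMLP(config.stage_train(5)).fit(X, y, groups=subj)


def train_non_hierarchical(samples: Sequence[SamplePair], config: HierarchyConfig) -> SoftmaxMLP:
    """Single 11-class MLP over concatenated organ + vessel features."""
    labels = {s.label for s in samples}
    missing = set(ScanLocation) - labels
    if missing:
        raise DataError(f"non-hierarchical training data lacks labels: {sorted(l.value for l in missing)}")
    X = np.stack([non_hierarchical_features(s, config) for s in samples])
    y = np.array([s.label.value for s in samples])
    subj = np.array([s.subject_id for s in samples])
    return SoftmaxMLP(config.stage_train(6)).fit(X, y, groups=subj)


@dataclass
class HierarchyModel:
    level1: SoftmaxMLP
    group1: Group1Model
    group2: SoftmaxMLP
    config: HierarchyConfig


def train_hierarchy(samples: Sequence[SamplePair], config: HierarchyConfig) -> HierarchyModel:
    """Train all stages on one training set."""
    g1 = [s for s in samples if s.label in GROUP1_LABELS]
    g2 = [s for s in samples if s.label in GROUP2_LABELS]
    return HierarchyModel(
        level1=train_level1(samples, config),
        group1=train_group1(g1, config),
        group2=train_group2(g2, config),
        config=config,
    )


# ---------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------


def predict(
    pair: SamplePair, model: HierarchyModel, trace: Optional[dict] = None
) -> ScanLocation:
    """Route one (organ, vessel) pair through the hierarchy.

    ``trace``, if given, is filled with ``level1`` (the 8-class code),
    ``branch`` (which stage produced the label) and, on the group-1
    branch, ``knn_votes``.
    """
    config = model.config
    x1 = level1_features(pair, config)[None, :]
    l1 = RegionGroup(model.level1.predict(x1)[0])
    if trace is not None:
        trace["level1"] = l1.name
    if l1 is RegionGroup.GROUP_ST_RSPV_RSHV:
        xg = group1_features(pair, config)
        if config.group1_routing == "confidence":
            proba = model.group1.substep1.predict_proba(xg[None, :])[0]
            if proba.max() >= config.group1_confidence_threshold:
                if trace is not None:
                    trace["branch"] = "group1_substep1"
                    trace["knn_votes"] = ""
                return ScanLocation(model.group1.substep1.classes_[int(np.argmax(proba))])
        emb = model.group1.encoder.transform(xg[None, :])[0]
        label = knn_classify(emb, model.group1.refs, k=config.knn_k)
        if trace is not None:
            trace["branch"] = "group1_knn"
            dists = np.linalg.norm(model.group1.refs.embeddings - emb[None, :], axis=1)
            order = np.argsort(dists, kind="stable")[: config.knn_k]
            trace["knn_votes"] = "|".join(model.group1.refs.labels[i].value for i in order)
        return label
    if l1 is RegionGroup.GROUP_SL_EBL:
        xi = group2_image_features(pair, config)
        if trace is not None:
            trace["branch"] = "group2"
        return ScanLocation(model.group2.predict(xi[None, :])[0])
    if trace is not None:
        trace["branch"] = "level1"
    return ScanLocation(l1.value)


def predict_batch(
    pairs: Sequence[SamplePair], model: HierarchyModel, paths: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Predict many pairs; one row per input with routing metadata."""
    rows = []
    for i, pair in enumerate(pairs):
        trace: dict = {"knn_votes": ""}
        label = predict(pair, model, trace)
        rows.append(
            {
                "path": paths[i] if paths is not None else str(i),
                "predicted_label": label.value,
                "level1_code": trace["level1"],
                "branch": trace["branch"],
                "knn_votes": trace.get("knn_votes", ""),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# comparison harness plumbing
# ---------------------------------------------------------------------


def make_run_mode(samples: Sequence[SamplePair], base_config: HierarchyConfig):
    """Adapter for :func:`liverscan.evaluation.compare_modes`.

    Returns ``run(mode, train_subjects, test_subjects, seed)`` supporting
    modes ``hierarchical``, ``non_hierarchical`` (all 11 labels) and
    ``substep1``, ``substep2`` (restricted to the ST/RSPV/RSHV group).
    """

    def run(mode: str, train_subjects, test_subjects, seed: int):
        config = replace(base_config, seed=seed)
        train = [s for s in samples if s.subject_id in train_subjects]
        test = [s for s in samples if s.subject_id in test_subjects]
        if mode == "hierarchical":
            model = train_hierarchy(train, config)
            return [(s.label, predict(s, model)) for s in test]
        if mode == "non_hierarchical":
            clf = train_non_hierarchical(train, config)
            X = np.stack([non_hierarchical_features(s, config) for s in test])
            preds = clf.predict(X)
            return [(s.label, ScanLocation(p)) for s, p in zip(test, preds)]
        if mode in ("substep1", "substep2"):
            train_g1 = [s for s in train if s.label in GROUP1_LABELS]
            test_g1 = [s for s in test if s.label in GROUP1_LABELS]
            g1 = train_group1(train_g1, config)
            X = np.stack([group1_features(s, config) for s in test_g1])
            if mode == "substep1":
                preds = g1.substep1.predict(X)
                return [(s.label, ScanLocation(p)) for s, p in zip(test_g1, preds)]
            emb = g1.encoder.transform(X)
            return [
                (s.label, knn_classify(e, g1.refs, k=config.knn_k))
                for s, e in zip(test_g1, emb)
            ]
        raise ValidationError(f"unknown mode: {mode}")

    return run


# ---------------------------------------------------------------------
# model bundle I/O
# ---------------------------------------------------------------------


def _mlp_to_npz(mlp: SoftmaxMLP, path: Path) -> None:
    state = mlp.state_dict()
    arrays = {"mu": state["mu"], "sd": state["sd"],
              "classes": np.array([str(c) for c in state["classes"]]),
              "hidden": np.array(state["hidden"])}
    for i, layer in enumerate(state["net"]):
        for attr, val in layer.items():
            arrays[f"net{i}__{attr}"] = val
    np.savez(path, **arrays)


def _mlp_from_npz(path: Path, train_config: TrainConfig) -> SoftmaxMLP:
    data = np.load(path, allow_pickle=False)
    n_layers = 1 + max(int(k.split("__")[0][3:]) for k in data.files if k.startswith("net"))
    net = [dict() for _ in range(n_layers)]
    for k in data.files:
        if k.startswith("net"):
            i, attr = k.split("__")
            net[int(i[3:])][attr] = data[k]
    state = {"net": net, "mu": data["mu"], "sd": data["sd"],
             "classes": data["classes"], "hidden": int(data["hidden"])}
    return SoftmaxMLP.from_state(state, replace(train_config, hidden=int(data["hidden"])))


def _encoder_to_npz(enc: TripletEncoder, path: Path) -> None:
    state = enc.state_dict()
    arrays = {
        "mu": state["mu"],
        "sd": state["sd"],
        "use_skip": state["use_skip"],
        "cfg": np.array(
            [
                state["config"]["embedding_dim"],
                state["config"]["hidden"],
                state["config"]["margin"],
                state["config"]["leaky_slope"],
                float(state["config"]["l2_normalize"]),
                float(state["config"]["residual"]),
            ]
        ),
    }
    if "pca_proj" in state:
        arrays["pca_mean"] = state["pca_mean"]
        arrays["pca_proj"] = state["pca_proj"]
    for i, layer in enumerate(state["net"]):
        for attr, val in layer.items():
            arrays[f"net{i}__{attr}"] = val
    np.savez(path, **arrays)


def _encoder_from_npz(path: Path) -> TripletEncoder:
    data = np.load(path, allow_pickle=False)
    n_layers = 1 + max(int(k.split("__")[0][3:]) for k in data.files if k.startswith("net"))
    net = [dict() for _ in range(n_layers)]
    for k in data.files:
        if k.startswith("net"):
            i, attr = k.split("__")
            net[int(i[3:])][attr] = data[k]
    cfg = data["cfg"]
    state = {
        "net": net,
        "mu": data["mu"],
        "sd": data["sd"],
        "use_skip": data["use_skip"],
        "config": {
            "embedding_dim": int(cfg[0]),
            "hidden": int(cfg[1]),
            "margin": float(cfg[2]),
            "leaky_slope": float(cfg[3]),
            "l2_normalize": bool(cfg[4]),
            "residual": bool(cfg[5]),
        },
    }
    if "pca_proj" in data.files:
        state["pca_mean"] = data["pca_mean"]
        state["pca_proj"] = data["pca_proj"]
    return TripletEncoder.from_state(state)


def save_model_bundle(model: HierarchyModel, out_dir) -> Path:
    """Serialize all stages + config into a bundle directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _mlp_to_npz(model.level1, out_dir / "level1.npz")
    _mlp_to_npz(model.group1.substep1, out_dir / "group1_substep1.npz")
    _mlp_to_npz(model.group2, out_dir / "group2.npz")
    _encoder_to_npz(model.group1.encoder, out_dir / "group1_encoder.npz")
    write_reference_set(model.group1.refs, out_dir / "group1_refs.h5")
    cfg = model.config
    (out_dir / "config.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "level1_parts": list(cfg.level1_parts),
                "group1_organ_parts": list(cfg.group1_organ_parts),
                "group1_organ_geometric_classes": (
                    None if cfg.group1_organ_geometric_classes is None
                    else list(cfg.group1_organ_geometric_classes)
                ),
                "group1_vessel_parts": list(cfg.group1_vessel_parts),
                "group1_routing": cfg.group1_routing,
                "group1_confidence_threshold": cfg.group1_confidence_threshold,
                "knn_k": cfg.knn_k,
                "grid": list(cfg.grid),
                "tsne_perplexity": cfg.tsne_perplexity,
                "group2_side": cfg.group2_side,
                "group2_pool": cfg.group2_pool,
                "clear_fraction": model.group1.clear_fraction,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return out_dir


def load_model_bundle(in_dir) -> HierarchyModel:
    in_dir = Path(in_dir)
    cfg_data = json.loads((in_dir / "config.json").read_text())
    config = HierarchyConfig(
        seed=int(cfg_data["seed"]),
        level1_parts=tuple(cfg_data["level1_parts"]),
        group1_organ_parts=tuple(cfg_data["group1_organ_parts"]),
        group1_organ_geometric_classes=(
            None if cfg_data["group1_organ_geometric_classes"] is None
            else tuple(cfg_data["group1_organ_geometric_classes"])
        ),
        group1_vessel_parts=tuple(cfg_data["group1_vessel_parts"]),
        group1_routing=cfg_data["group1_routing"],
        group1_confidence_threshold=cfg_data["group1_confidence_threshold"],
        knn_k=int(cfg_data["knn_k"]),
        grid=tuple(cfg_data["grid"]),
        tsne_perplexity=cfg_data["tsne_perplexity"],
        group2_side=int(cfg_data["group2_side"]),
        group2_pool=int(cfg_data["group2_pool"]),
    )
    tc = config.train
    group1 = Group1Model(
        substep1=_mlp_from_npz(in_dir / "group1_substep1.npz", tc),
        encoder=_encoder_from_npz(in_dir / "group1_encoder.npz"),
        refs=read_reference_set(in_dir / "group1_refs.h5"),
        clear_fraction=float(cfg_data.get("clear_fraction", float("nan"))),
    )
    return HierarchyModel(
        level1=_mlp_from_npz(in_dir / "level1.npz", tc),
        group1=group1,
        group2=_mlp_from_npz(in_dir / "group2.npz", tc),
        config=config,
    )
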