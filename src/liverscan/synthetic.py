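"""Synthetic segmentation-artifact generator for the 11 scan locations.

Real inputs to this pipeline are per-image outputs of organ and vessel
segmentation networks on liver ultrasound frames; the clinical datasets
behind them are private.  This module generates artifact pairs with the
statistical structure every pipeline stage relies on:

* class-dependent organ layout — which of liver / kidney / gallbladder is
  visible, where, how large and how elongated — rendered as elliptical
  blobs on a speckle background;
* class-dependent vessel morphology — quadratic Bezier strokes with
  branch-count, curvature and echogenicity ranges per scan location;
* mask logits as Gaussian-blurred signed-distance maps of each mask, so
  they carry realistic negative values outside the structure;
* low-dimensional embedding structure: per-segment query embeddings and
  encoder feature maps drawn from label-conditional Gaussians with
  per-subject mean offsets (inter-subject variability);
* an ``ambiguity_overlap`` dial for the within-group confusability of the
  {ST, RSPV, RSHV} and {SL, EBL} groups: each sample draws a partner
  class in its group and a mixing weight t ~ U(0, overlap) pulling its
  vessel geometry, embeddings and feature map toward the partner's, with
  noise growing with t — the probe-motion phenomenon where a frame
  labeled one view increasingly resembles a neighboring view.  Clear
  frames (small t) stay separable; strongly mixed frames are genuinely
  confusable from segmentation-derived features alone, which corrupts
  classifiers trained on all frames but not an encoder trained on clear
  frames only.  Vessel echogenicity is NOT mixed: like real echo
  texture, it survives when the derived features blur, which is what the
  image-based SL/EBL classifier exploits.

Defaults: 128 x 128 rasters, 32-channel query embeddings and feature
maps, organ model with classes (background, liver, kidney, gallbladder),
vessel model with (background, vessel).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.draw import disk, ellipse

from .segmentation_io import (
    ScanLocation,
    SegmentationArtifact,
    ValidationError,
    write_artifact,
    write_manifest,
    read_manifest,
    read_artifact,
)

# model dimensions (desk scale)
IMAGE_SIZE = 128
C_Q = 32
C_F = 32
FEATURE_HW = 4
ORGAN_CLASSES = {"liver": 1, "kidney": 2, "gallbladder": 3}
N_ORGAN = 4
N_VESSEL = 2

GROUP1 = (ScanLocation.ST, ScanLocation.RSPV, ScanLocation.RSHV)
GROUP2 = (ScanLocation.SL, ScanLocation.EBL)


@dataclass(frozen=True)
class OrganSpec:
    """Geometry of one organ at one scan location (fraction-of-image units)."""

    presence: float = 0.0
    centroid: tuple[float, float] = (0.5, 0.5)  # (fx, fy)
    centroid_spread: float = 0.02
    area: float = 0.15
    area_spread: float = 0.02
    eccentricity: tuple[float, float] = (1.2, 1.8)  # rx/ry aspect range
    rotation: float = 0.0  # radians, mean orientation
    intensity: float = 90.0


@dataclass(frozen=True)
class VesselSpec:
    """Vessel stroke geometry at one scan location."""

    presence: float = 0.0
    centroid: tuple[float, float] = (0.5, 0.45)
    centroid_spread: float = 0.03
    branch_count: tuple[int, int] = (1, 2)
    curvature: tuple[float, float] = (0.05, 0.2)  # control-point offset, fraction units
    length: float = 0.35  # stroke span, fraction of image side
    width: float = 2.5  # stamp radius, pixels
    intensity: float = 55.0  # echogenicity inside the vessel
    intensity_spread: float = 8.0


@dataclass(frozen=True)
class ClassGeometrySpec:
    """Everything the generator needs for one scan location."""

    label: ScanLocation
    organs: dict  # organ name -> OrganSpec
    vessel: VesselSpec
    ambiguity_overlap: float = 0.0
    group_partners: tuple = ()  # labels sharing a confusable group, incl. self
    mix_vessels: Optional[dict] = None  # partner label -> VesselSpec
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.ambiguity_overlap <= 1.0:
            raise ValidationError("ambiguity_overlap must lie in [0, 1]")
        for name, org in self.organs.items():
            if not 0.0 <= org.presence <= 1.0:
                raise ValidationError(f"{self.label.value}/{name}: presence must be in [0,1]")
            if not 0.0 < org.area < 1.0:
                raise ValidationError(f"{self.label.value}/{name}: area fraction must be in (0,1)")
        if not 0.0 <= self.vessel.presence <= 1.0:
            raise ValidationError(f"{self.label.value}: vessel presence must be in [0,1]")
        if self.label is ScanLocation.LK and self.organs.get("kidney", OrganSpec()).presence != 1.0:
            raise ValidationError("LK spec must have kidney presence 1.0")
        if (
            self.label is ScanLocation.GBL
            and self.organs.get("gallbladder", OrganSpec()).presence != 1.0
        ):
            raise ValidationError("GBL spec must have gallbladder presence 1.0")


@dataclass
class SamplePair:
    """One synthetic frame: the organ-model and vessel-model artifacts."""

    organ: SegmentationArtifact
    vessel: SegmentationArtifact
    label: ScanLocation
    subject_id: str


# ---------------------------------------------------------------------
# default spec set: the 11 locations
# ---------------------------------------------------------------------


def _liver(cx, cy, area=0.18, ecc=(1.3, 1.9), rot=0.0, presence=1.0):
    return OrganSpec(
        presence=presence, centroid=(cx, cy), area=area, eccentricity=ecc,
        rotation=rot, intensity=95.0,
    )


def default_spec_set(ambiguity_overlap: float = 0.0, seed: int = 0) -> dict:
    """Per-location geometry specs.

    The eight level-1 regions are separable from organ layout alone;
    within the {ST,RSPV,RSHV} and {SL,EBL} groups the organ layout is
    shared and discrimination rests on vessel morphology/embeddings
    (degraded by ``ambiguity_overlap``) and, for SL vs EBL, vessel
    echogenicity.
    """
    L = ScanLocation
    specs: dict[ScanLocation, ClassGeometrySpec] = {}

    # --- group 1: right-lobe views; identical organ layout, vessels differ
    g1_organs = {"liver": _liver(0.52, 0.42, area=0.22, ecc=(1.4, 1.8))}
    g1_vessels = {
        L.ST: VesselSpec(1.0, centroid=(0.40, 0.32), branch_count=(3, 4),
                         curvature=(0.04, 0.10), length=0.40, width=2.2, intensity=50.0),
        L.RSPV: VesselSpec(1.0, centroid=(0.62, 0.50), branch_count=(2, 2),
                           curvature=(0.12, 0.22), length=0.34, width=3.2, intensity=58.0),
        L.RSHV: VesselSpec(1.0, centroid=(0.46, 0.62), branch_count=(3, 3),
                           curvature=(0.02, 0.06), length=0.42, width=2.6, intensity=46.0),
    }
    # --- group 2: similar layouts, vessels differ mainly in echogenicity
    g2_organs = {"liver": _liver(0.42, 0.38, area=0.16, ecc=(2.0, 2.6))}
    g2_vessels = {
        L.SL: VesselSpec(1.0, centroid=(0.50, 0.55), branch_count=(1, 1),
                         curvature=(0.03, 0.08), length=0.45, width=2.8, intensity=42.0),
        L.EBL: VesselSpec(1.0, centroid=(0.53, 0.57), branch_count=(2, 2),
                          curvature=(0.05, 0.12), length=0.30, width=3.4, intensity=168.0),
    }

    for lab in GROUP1:
        specs[lab] = ClassGeometrySpec(
            label=lab, organs=dict(g1_organs), vessel=g1_vessels[lab],
            ambiguity_overlap=ambiguity_overlap, group_partners=GROUP1,
            mix_vessels={l: g1_vessels[l] for l in GROUP1 if l is not lab},
            seed=seed,
        )
    for lab in GROUP2:
        specs[lab] = ClassGeometrySpec(
            label=lab, organs=dict(g2_organs), vessel=g2_vessels[lab],
            ambiguity_overlap=ambiguity_overlap, group_partners=GROUP2,
            mix_vessels={l: g2_vessels[l] for l in GROUP2 if l is not lab},
            seed=seed,
        )

    # --- the six singleton regions: distinct organ layouts
    specs[L.RSLT] = ClassGeometrySpec(
        label=L.RSLT,
        organs={"liver": _liver(0.62, 0.52, area=0.30, ecc=(1.1, 1.4))},
        vessel=VesselSpec(presence=0.3, centroid=(0.6, 0.5), length=0.2),
        seed=seed,
    )
    specs[L.LD] = ClassGeometrySpec(
        label=L.LD,
        organs={"liver": _liver(0.50, 0.24, area=0.20, ecc=(2.2, 2.8))},
        vessel=VesselSpec(presence=0.2, centroid=(0.5, 0.3), length=0.2),
        seed=seed,
    )
    specs[L.GBL] = ClassGeometrySpec(
        label=L.GBL,
        organs={
            "liver": _liver(0.40, 0.35, area=0.14, presence=0.9),
            "gallbladder": OrganSpec(1.0, centroid=(0.56, 0.60), area=0.05,
                                     eccentricity=(2.4, 3.0), rotation=0.6, intensity=45.0),
        },
        vessel=VesselSpec(presence=0.2, centroid=(0.45, 0.4), length=0.2),
        seed=seed,
    )
    specs[L.RIA] = ClassGeometrySpec(
        label=L.RIA,
        organs={"liver": _liver(0.34, 0.46, area=0.24, ecc=(1.6, 2.0), rot=0.7)},
        vessel=VesselSpec(presence=0.5, centroid=(0.35, 0.45), length=0.25),
        seed=seed,
    )
    specs[L.RIP] = ClassGeometrySpec(
        label=L.RIP,
        organs={"liver": _liver(0.68, 0.62, area=0.24, ecc=(1.6, 2.0), rot=-0.7)},
        vessel=VesselSpec(presence=0.5, centroid=(0.65, 0.6), length=0.25),
        seed=seed,
    )
    specs[L.LK] = ClassGeometrySpec(
        label=L.LK,
        organs={
            "liver": _liver(0.40, 0.38, area=0.18),
            "kidney": OrganSpec(1.0, centroid=(0.64, 0.64), area=0.09,
                                eccentricity=(1.8, 2.2), rotation=0.4, intensity=120.0),
        },
        vessel=VesselSpec(presence=0.3, centroid=(0.5, 0.5), length=0.2),
        seed=seed,
    )
    for spec in specs.values():
        spec.validate()
    return specs


def overlap_spec_set(ambiguity_overlap: float = 0.6, seed: int = 0) -> dict:
    """The engineered-overlap study condition used for the directional
    sub-step and hierarchy-vs-flat comparisons."""
    return default_spec_set(ambiguity_overlap=ambiguity_overlap, seed=seed)


# ---------------------------------------------------------------------
# latent means (label-, group- and subject-conditional)
# ---------------------------------------------------------------------

_LABEL_INDEX = {lab: i for i, lab in enumerate(ScanLocation)}


def _mean_rng(spec_seed: int, tag: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, tag, key]))


def _group_key(spec: ClassGeometrySpec) -> int:
    labels = spec.group_partners or (spec.label,)
    return int(sum(1 << _LABEL_INDEX[l] for l in labels))


def _organ_query_means(spec: ClassGeometrySpec) -> np.ndarray:
    # shared within a confusable group: organ info cannot split the group
    return _mean_rng(spec.seed, 1, _group_key(spec)).normal(0.0, 2.5, size=(C_Q, N_ORGAN))


def _vessel_query_mean_for(label: ScanLocation, spec_seed: int) -> np.ndarray:
    return _mean_rng(spec_seed, 2, _LABEL_INDEX[label]).normal(0.0, 2.5, size=C_Q)


def _feature_map_mean(spec: ClassGeometrySpec, vessel: bool) -> np.ndarray:
    tag = 4 if vessel else 3
    key = _LABEL_INDEX[spec.label] if vessel else _group_key(spec)
    return _mean_rng(spec.seed, tag, key).normal(0.0, 1.5, size=(C_F, FEATURE_HW, FEATURE_HW))


def _subject_offset(subject_id: str, dim: int, scale: float) -> np.ndarray:
    srng = np.random.default_rng(zlib.crc32(subject_id.encode()) & 0x7FFFFFFF)
    return srng.normal(0.0, scale, size=dim)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------


def _stamp_bezier(mask: np.ndarray, p0, p1, p2, width: float, rng) -> None:
    h, w = mask.shape
    ts = np.linspace(0.0, 1.0, 120)
    pts = (
        (1 - ts)[:, None] ** 2 * np.asarray(p0)[None]
        + 2 * (1 - ts)[:, None] * ts[:, None] * np.asarray(p1)[None]
        + ts[:, None] ** 2 * np.asarray(p2)[None]
    )
    widths = np.clip(width + rng.normal(0.0, 0.3, size=len(ts)), 0.8, None)
    for (x, y), r in zip(pts, widths):
        rr, cc = disk((y, x), r, shape=(h, w))
        mask[rr, cc] = True


def _render_vessel_mask(vs: VesselSpec, size: int, rng, subj_shift) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    cx = (vs.centroid[0] + subj_shift[0]) * size + rng.normal(0, vs.centroid_spread * size)
    cy = (vs.centroid[1] + subj_shift[1]) * size + rng.normal(0, vs.centroid_spread * size)
    n_branches = int(rng.integers(vs.branch_count[0], vs.branch_count[1] + 1))
    span = vs.length * size
    base_angle = rng.uniform(0, np.pi)
    for b in range(max(n_branches, 1)):
        ang = base_angle + b * (np.pi / max(n_branches, 1)) + rng.normal(0, 0.15)
        dx, dy = np.cos(ang), np.sin(ang)
        p0 = (cx - dx * span / 2, cy - dy * span / 2)
        p2 = (cx + dx * span / 2, cy + dy * span / 2)
        curv = rng.uniform(*vs.curvature) * size * rng.choice([-1.0, 1.0])
        p1 = (cx - dy * curv, cy + dx * curv)
        _stamp_bezier(mask, p0, p1, p2, vs.width, rng)
    return mask


def _render_organ_mask(org: OrganSpec, size: int, rng, subj_shift) -> np.ndarray:
    cx = (org.centroid[0] + subj_shift[0]) * size + rng.normal(0, org.centroid_spread * size)
    cy = (org.centroid[1] + subj_shift[1]) * size + rng.normal(0, org.centroid_spread * size)
    area = max(org.area + rng.normal(0, org.area_spread), 0.01) * size * size
    aspect = rng.uniform(*org.eccentricity)
    ry = np.sqrt(area / (np.pi * aspect))
    rx = aspect * ry
    rot = org.rotation + rng.normal(0, 0.1)
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = ellipse(cy, cx, ry, rx, shape=(size, size), rotation=rot)
    mask[rr, cc] = True
    return mask


def _signed_distance_logits(masks: list[np.ndarray], rng) -> np.ndarray:
    """Per-channel blurred signed distance (positive inside), with the
    background channel covering everything unclaimed."""
    fg = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        fg |= m
    channels = [~fg] + masks
    out = np.empty((len(channels),) + masks[0].shape)
    for i, m in enumerate(channels):
        if m.all():
            sd = distance_transform_edt(m)
        elif not m.any():
            sd = -distance_transform_edt(~m)
        else:
            sd = distance_transform_edt(m) - distance_transform_edt(~m)
        out[i] = gaussian_filter(sd, sigma=2.0) * 0.35 + rng.normal(0.0, 0.2, size=m.shape)
    return out


def _mix(a, b, t):
    return (1.0 - t) * np.asarray(a, dtype=float) + t * np.asarray(b, dtype=float)


def _mixed_vessel_spec(
    spec: ClassGeometrySpec, partner: Optional[ScanLocation], t: float
) -> VesselSpec:
    vs = spec.vessel
    mv = (spec.mix_vessels or {}).get(partner)
    if mv is None or t <= 0:
        return vs
    # echogenicity deliberately NOT mixed (see module docstring)
    return VesselSpec(
        presence=vs.presence,
        centroid=(float(_mix(vs.centroid[0], mv.centroid[0], t)),
                  float(_mix(vs.centroid[1], mv.centroid[1], t))),
        centroid_spread=float(_mix(vs.centroid_spread, mv.centroid_spread, t)),
        branch_count=(
            int(round(_mix(vs.branch_count[0], mv.branch_count[0], t))),
            int(round(_mix(vs.branch_count[1], mv.branch_count[1], t))),
        ),
        curvature=(float(_mix(vs.curvature[0], mv.curvature[0], t)),
                   float(_mix(vs.curvature[1], mv.curvature[1], t))),
        length=float(_mix(vs.length, mv.length, t)),
        width=float(_mix(vs.width, mv.width, t)),
        intensity=vs.intensity,
        intensity_spread=vs.intensity_spread,
    )


def generate_scan_sample(
    label: ScanLocation,
    spec: ClassGeometrySpec,
    subject_id: str,
    rng: np.random.Generator,
    size: int = IMAGE_SIZE,
) -> tuple[SegmentationArtifact, SegmentationArtifact]:
    """Render one (organ artifact, vessel artifact) pair.

    Deterministic for a fixed (label, spec, subject_id, rng state).
    """
    spec.validate()
    subj_xy = _subject_offset(subject_id, 2, 0.015)
    subj_emb = _subject_offset(subject_id + ":emb", C_Q, 0.4)

    # per-sample ambiguity: draw a partner class in the group and a mixing
    # weight t ~ U(0, overlap); the sample's vessel geometry, embeddings and
    # feature map drift toward the partner's, with noise growing with t.
    partners = [l for l in spec.group_partners if l is not label and ScanLocation(l) != label]
    if spec.ambiguity_overlap > 0 and partners:
        t = float(rng.uniform(0.0, spec.ambiguity_overlap))
        partner: Optional[ScanLocation] = partners[int(rng.integers(len(partners)))]
    else:
        t, partner = 0.0, None
    noise_scale = 1.0 + 1.5 * t

    # ---------------- image base: speckle
    image = rng.normal(42.0, 12.0, size=(size, size))

    # ---------------- organ artifact
    organ_masks = [np.zeros((size, size), dtype=bool) for _ in range(N_ORGAN - 1)]
    for name, org in spec.organs.items():
        if rng.uniform() < org.presence:
            m = _render_organ_mask(org, size, rng, subj_xy)
            organ_masks[ORGAN_CLASSES[name] - 1] = m
            image[m] = org.intensity + rng.normal(0.0, 10.0, size=int(m.sum()))

    # ---------------- vessel artifact geometry
    vspec = _mixed_vessel_spec(spec, partner, t)
    if rng.uniform() < vspec.presence:
        vmask = _render_vessel_mask(vspec, size, rng, subj_xy)
    else:
        vmask = np.zeros((size, size), dtype=bool)
    if vmask.any():
        image[vmask] = vspec.intensity + rng.normal(
            0.0, vspec.intensity_spread, size=int(vmask.sum())
        )
    image = np.clip(image, 0, 255).astype(np.uint8)

    organ_cm = np.zeros((size, size), dtype=np.int32)
    for ci, m in enumerate(organ_masks, start=1):
        organ_cm[m] = ci
    vessel_cm = vmask.astype(np.int32)

    organ_logits = _signed_distance_logits(organ_masks, rng)
    vessel_logits = _signed_distance_logits([vmask], rng)

    # ---------------- embeddings / feature maps / class scores
    organ_q_mean = _organ_query_means(spec)
    organ_q = organ_q_mean + rng.normal(0.0, 1.0, size=(C_Q, N_ORGAN))
    organ_q += subj_emb[:, None]
    for ci, m in enumerate(organ_masks, start=1):
        if not m.any():  # absent class: its query carries no class signal
            organ_q[:, ci] = rng.normal(0.0, 1.0, size=C_Q) + subj_emb

    v_mean_self = _vessel_query_mean_for(label, spec.seed)
    v_mean_target = (
        _vessel_query_mean_for(partner, spec.seed) if partner is not None else v_mean_self
    )
    v_mean = _mix(v_mean_self, v_mean_target, t)
    vessel_q = rng.normal(0.0, noise_scale, size=(C_Q, N_VESSEL))
    vessel_q[:, 1] += v_mean + subj_emb
    vessel_q[:, 0] += _mean_rng(spec.seed, 5, 0).normal(0.0, 1.0, size=C_Q)

    organ_fmap = _feature_map_mean(spec, vessel=False) + rng.normal(
        0.0, 0.5, size=(C_F, FEATURE_HW, FEATURE_HW)
    )
    vf_self = _feature_map_mean(spec, vessel=True)
    if partner is not None:
        vf_target = _mean_rng(spec.seed, 4, _LABEL_INDEX[partner]).normal(
            0.0, 1.5, size=(C_F, FEATURE_HW, FEATURE_HW)
        )
    else:
        vf_target = vf_self
    vessel_fmap = _mix(vf_self, vf_target, t) + rng.normal(
        0.0, 0.5 * noise_scale, size=(C_F, FEATURE_HW, FEATURE_HW)
    )

    def scores(masks, n):
        cs = rng.normal(0.0, 0.5, size=(n, n + 1))
        cs[0, 0] += 4.0
        for ci in range(1, n):
            if masks[ci - 1].any():
                cs[ci, ci] += 4.0
            else:
                cs[ci, n] += 4.0  # "no object"
        return cs

    organ = SegmentationArtifact(
        image=image, class_map=organ_cm, n_classes=N_ORGAN,
        mask_logits=organ_logits, query_embeddings=organ_q,
        feature_map=organ_fmap, class_scores=scores(organ_masks, N_ORGAN),
        subject_id=subject_id, label=label,
    )
    vessel = SegmentationArtifact(
        image=image, class_map=vessel_cm, n_classes=N_VESSEL,
        mask_logits=vessel_logits, query_embeddings=vessel_q,
        feature_map=vessel_fmap, class_scores=scores([vmask], N_VESSEL),
        subject_id=subject_id, label=label,
    )
    return organ, vessel


# ---------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------


def generate_samples(
    spec_set: dict,
    n_per_class: int,
    subjects: Sequence[str],
    seed: int = 0,
    size: int = IMAGE_SIZE,
) -> list[SamplePair]:
    """Balanced in-memory dataset: ``n_per_class`` pairs per location,
    subjects assigned round-robin within each class (counts differ by at
    most one).  Fully determined by ``seed``."""
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if len(subjects) < 2:
        raise ValidationError("need at least 2 subjects")
    samples = []
    for label in ScanLocation:
        if label not in spec_set:
            continue
        spec = spec_set[label]
        for j in range(n_per_class):
            subject = subjects[j % len(subjects)]
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, _LABEL_INDEX[label], j])
            )
            organ, vessel = generate_scan_sample(label, spec, subject, rng, size=size)
            samples.append(SamplePair(organ=organ, vessel=vessel, label=label, subject_id=subject))
    return samples


def generate_dataset(
    out_dir,
    spec_set: dict,
    n_per_class: int,
    subjects: Sequence[str],
    seed: int = 0,
    size: int = IMAGE_SIZE,
) -> Path:
    """Write artifact bundles plus a ``manifest.csv`` (path,subject_id,label)
    under ``out_dir``; the manifest path column points at the organ bundle,
    the vessel bundle is the sibling ``*_vessel.h5``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(spec_set, n_per_class, subjects, seed=seed, size=size)
    rows = []
    counters: dict[str, int] = {}
    for s in samples:
        j = counters.get(s.label.value, 0)
        counters[s.label.value] = j + 1
        stem = f"{s.label.value}_{j:04d}"
        organ_path = out_dir / f"{stem}_organ.h5"
        write_artifact(s.organ, organ_path)
        write_artifact(s.vessel, out_dir / f"{stem}_vessel.h5")
        rows.append((organ_path.name, s.subject_id, s.label.value))
    return write_manifest(rows, out_dir / "manifest.csv")


def vessel_path_for(organ_path) -> Path:
    organ_path = Path(organ_path)
    if not organ_path.name.endswith("_organ.h5"):
        raise ValidationError(f"not an organ bundle path: {organ_path}")
    return organ_path.with_name(organ_path.name[: -len("_organ.h5")] + "_vessel.h5")


def load_pairs(manifest_path) -> list[SamplePair]:
    """Load the (organ, vessel) pairs a manifest describes."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    pairs = []
    for _, row in df.iterrows():
        organ = read_artifact(base / row["path"])
        vessel = read_artifact(vessel_path_for(base / row["path"]))
        pairs.append(
            SamplePair(
                organ=organ, vessel=vessel,
                label=ScanLocation(row["label"]), subject_id=str(row["subject_id"]),
            )
        )
    return pairs


# ---------------------------------------------------------------------
# morphological interpolation (probe-motion stand-in)
# ---------------------------------------------------------------------


def _blend_class_maps(cm_a, cm_b, n_classes: int, t: float) -> np.ndarray:
    """Distance-field blend: interpolate per-class signed distances and
    re-label each pixel by the largest positive blended field."""
    fields = np.empty((n_classes - 1,) + cm_a.shape)
    for ci in range(1, n_classes):
        for k, cm in enumerate((cm_a, cm_b)):
            m = cm == ci
            if m.all():
                sd = distance_transform_edt(m)
            elif not m.any():
                sd = -distance_transform_edt(~m)
            else:
                sd = distance_transform_edt(m) - distance_transform_edt(~m)
            if k == 0:
                acc = (1.0 - t) * sd
            else:
                acc = acc + t * sd
        fields[ci - 1] = acc
    out = np.zeros(cm_a.shape, dtype=np.int32)
    best = np.max(fields, axis=0)
    arg = np.argmax(fields, axis=0) + 1
    out[best > 0] = arg[best > 0]
    return out


def make_ambiguous_pair(
    sample_a: SamplePair, sample_b: SamplePair, t: float, rng: np.random.Generator
) -> SamplePair:
    """Interpolate two frames at mixing weight ``t``: masks by
    distance-field blending, all dense tensors and embeddings convexly;
    the label comes from the nearer endpoint (t < 0.5 -> a)."""
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"t must lie in [0, 1], got {t}")
    if sample_a.organ.image.shape != sample_b.organ.image.shape:
        raise ValidationError("samples must share image dimensions")
    src = sample_a if t < 0.5 else sample_b

    def blend_art(a: SegmentationArtifact, b: SegmentationArtifact) -> SegmentationArtifact:
        if t == 0.0:
            return a
        if t == 1.0:
            return b
        return SegmentationArtifact(
            image=np.clip(_mix(a.image, b.image, t), 0, 255).astype(np.uint8),
            class_map=_blend_class_maps(a.class_map, b.class_map, a.n_classes, t),
            n_classes=a.n_classes,
            mask_logits=_mix(a.mask_logits, b.mask_logits, t),
            query_embeddings=_mix(a.query_embeddings, b.query_embeddings, t),
            feature_map=_mix(a.feature_map, b.feature_map, t),
            class_scores=_mix(a.class_scores, b.class_scores, t),
            subject_id=src.subject_id,
            label=src.label,
        )

    return SamplePair(
        organ=blend_art(sample_a.organ, sample_b.organ),
        vessel=blend_art(sample_a.vessel, sample_b.vessel),
        label=src.label,
        subject_id=src.subject_id,
    )
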