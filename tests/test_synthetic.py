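"""Synthetic generator: determinism, label-conditional structure,
dataset bookkeeping and morphological interpolation."""

import hashlib

import numpy as np
import pytest

import liverscan as ls
from liverscan import (
    ScanLocation,
    ValidationError,
    default_spec_set,
    generate_dataset,
    generate_samples,
    generate_scan_sample,
    load_pairs,
    make_ambiguous_pair,
)
from liverscan.synthetic import GROUP1, ClassGeometrySpec, OrganSpec, VesselSpec

from conftest import SUBJECTS


class TestSpecValidation:
    def test_default_specs_cover_all_locations(self, separable_specs):
        assert set(separable_specs) == set(ScanLocation)
        for spec in separable_specs.values():
            spec.validate()

    def test_lk_requires_kidney(self):
        bad = ClassGeometrySpec(
            label=ScanLocation.LK,
            organs={"liver": OrganSpec(presence=1.0, area=0.2)},
            vessel=VesselSpec(),
        )
        with pytest.raises(ValidationError, match="kidney"):
            bad.validate()

    def test_overlap_out_of_range_rejected(self):
        bad = ClassGeometrySpec(
            label=ScanLocation.LD,
            organs={"liver": OrganSpec(presence=1.0, area=0.2)},
            vessel=VesselSpec(),
            ambiguity_overlap=1.5,
        )
        with pytest.raises(ValidationError):
            bad.validate()


class TestGenerateScanSample:
    def test_lk_always_has_kidney(self, separable_specs):
        spec = separable_specs[ScanLocation.LK]
        for seed in range(5):
            organ, _ = generate_scan_sample(
                ScanLocation.LK, spec, "subjA", np.random.default_rng(seed)
            )
            assert (organ.class_map == 2).sum() > 0  # kidney is class 2

    def test_deterministic_given_rng_state(self, separable_specs):
        spec = separable_specs[ScanLocation.ST]
        a = generate_scan_sample(ScanLocation.ST, spec, "subjB", np.random.default_rng(9))
        b = generate_scan_sample(ScanLocation.ST, spec, "subjB", np.random.default_rng(9))
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_artifacts_pass_validation(self, small_dataset):
        for s in small_dataset[::7]:
            s.organ.validate()
            s.vessel.validate()

    def test_group1_vessel_centroids_separate_without_overlap(self, separable_specs):
        # pairwise centroid separation across the group >= 3 spread units
        cents = {}
        for lab in GROUP1:
            spec = separable_specs[lab]
            pts = []
            for i in range(100):
                _, vessel = generate_scan_sample(
                    lab, spec, "subjA", np.random.default_rng(1000 + i)
                )
                ys, xs = np.nonzero(vessel.class_map)
                if len(xs):
                    pts.append((xs.mean(), ys.mean()))
            cents[lab] = np.array(pts)
        spread = max(
            max(c.std(axis=0)) for c in cents.values()
        )
        labs = list(cents)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                gap = np.linalg.norm(cents[labs[i]].mean(axis=0) - cents[labs[j]].mean(axis=0))
                assert gap >= 3 * spread

    def test_presence_rates_match_spec(self, separable_specs):
        # GBL liver presence is 0.9; check within 3 standard errors over 500 draws
        spec = separable_specs[ScanLocation.GBL]
        hits = 0
        n = 500
        for i in range(n):
            organ, _ = generate_scan_sample(
                ScanLocation.GBL, spec, "subjC", np.random.default_rng(i)
            )
            hits += int((organ.class_map == 1).any())
        p = spec.organs["liver"].presence
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se


class TestGenerateDataset:
    def test_balanced_counts(self, separable_specs):
        samples = generate_samples(separable_specs, 3, SUBJECTS, seed=0)
        assert len(samples) == 33
        for lab in ScanLocation:
            assert sum(s.label is lab for s in samples) == 3

    def test_round_robin_subject_assignment(self, separable_specs):
        samples = generate_samples(separable_specs, 7, SUBJECTS, seed=0)
        for lab in ScanLocation:
            counts = {}
            for s in samples:
                if s.label is lab:
                    counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_same_seed_identical_manifest_bytes(self, separable_specs, tmp_path):
        m1 = generate_dataset(tmp_path / "d1", separable_specs, 2, SUBJECTS[:3], seed=4)
        m2 = generate_dataset(tmp_path / "d2", separable_specs, 2, SUBJECTS[:3], seed=4)
        assert hashlib.sha256(m1.read_bytes()).hexdigest() == hashlib.sha256(
            m2.read_bytes()
        ).hexdigest()

    def test_written_dataset_loads_back(self, separable_specs, tmp_path):
        manifest = generate_dataset(tmp_path / "d", separable_specs, 1, SUBJECTS[:2], seed=5)
        pairs = load_pairs(manifest)
        assert len(pairs) == 11
        in_memory = generate_samples(separable_specs, 1, SUBJECTS[:2], seed=5)
        for disk, mem in zip(pairs, in_memory):
            assert disk.label is mem.label
            assert disk.organ.equals(mem.organ)
            assert disk.vessel.equals(mem.vessel)

    def test_too_few_subjects_rejected(self, separable_specs):
        with pytest.raises(ValidationError):
            generate_samples(separable_specs, 2, ["only-one"], seed=0)


class TestAmbiguousPair:
    @pytest.fixture()
    def endpoints(self, small_dataset):
        a = next(s for s in small_dataset if s.label is ScanLocation.ST)
        b = next(s for s in small_dataset if s.label is ScanLocation.RSPV)
        return a, b

    def test_t0_is_first_endpoint(self, endpoints):
        a, b = endpoints
        mixed = make_ambiguous_pair(a, b, 0.0, np.random.default_rng(0))
        assert mixed.label is a.label
        assert mixed.organ.equals(a.organ)

    def test_t1_is_second_endpoint(self, endpoints):
        a, b = endpoints
        mixed = make_ambiguous_pair(a, b, 1.0, np.random.default_rng(0))
        assert mixed.label is b.label
        assert mixed.vessel.equals(b.vessel)

    def test_midpoint_embeddings_are_convex_blend(self, endpoints):
        a, b = endpoints
        mixed = make_ambiguous_pair(a, b, 0.5, np.random.default_rng(0))
        expected = 0.5 * a.vessel.query_embeddings + 0.5 * b.vessel.query_embeddings
        assert mixed.vessel.query_embeddings == pytest.approx(expected)

    def test_label_from_nearer_endpoint(self, endpoints):
        a, b = endpoints
        assert make_ambiguous_pair(a, b, 0.4, np.random.default_rng(0)).label is a.label
        assert make_ambiguous_pair(a, b, 0.6, np.random.default_rng(0)).label is b.label

    def test_t_outside_unit_interval_rejected(self, endpoints):
        a, b = endpoints
        with pytest.raises(ValidationError):
            make_ambiguous_pair(a, b, 1.2, np.random.default_rng(0))


class TestOverlapDial:
    def test_substep1_accuracy_decreases_with_overlap(self):
        """More engineered ambiguity must make the initial group-1
        classifier worse on held-out subjects (three overlap levels)."""
        from liverscan.hierarchy import GROUP1_LABELS, HierarchyConfig, group1_features
        from liverscan._nn import SoftmaxMLP, TrainConfig

        accs = []
        for overlap in (0.0, 0.5, 1.0):
            specs = ls.default_spec_set(ambiguity_overlap=overlap, seed=0)
            g1 = {k: v for k, v in specs.items() if k in GROUP1_LABELS}
            samples = generate_samples(g1, 20, SUBJECTS, seed=3)
            train = [s for s in samples if s.subject_id in SUBJECTS[:3]]
            test = [s for s in samples if s.subject_id in SUBJECTS[3:]]
            cfg = HierarchyConfig(seed=0)
            Xtr = np.stack([group1_features(s, cfg) for s in train])
            ytr = np.array([s.label.value for s in train])
            Xte = np.stack([group1_features(s, cfg) for s in test])
            yte = np.array([s.label.value for s in test])
            clf = SoftmaxMLP(TrainConfig(seed=0)).fit(
                Xtr, ytr, groups=np.array([s.subject_id for s in train])
            )
            accs.append(float((clf.predict(Xte) == yte).mean()))
        assert accs[0] >= accs[1] >= accs[2]
        assert accs[0] > accs[2]
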