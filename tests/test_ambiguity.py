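"""Triplet loss, metric encoder, t-SNE grid references and KNN voting."""

import numpy as np
import pytest

from liverscan import (
    ScanLocation,
    TripletEncoderConfig,
    knn_classify,
    select_reference_points,
    train_triplet_encoder,
    triplet_loss,
)
from liverscan.ambiguity import (
    _grid_cell,
    read_reference_set,
    reference_set_summary,
    write_reference_set,
)
from liverscan.geometry import ConfigurationError
from liverscan._nn import DataError


class TestTripletLoss:
    def test_identical_triplet_is_margin(self):
        a = np.ones(4)
        assert triplet_loss(a, a, a, margin=1.0) == 1.0

    def test_hinge_clamps_at_zero(self):
        a = np.zeros(2)
        n = np.array([np.sqrt(2.0), 0.0])  # |a-n|^2 = 2
        assert triplet_loss(a, a, n, margin=1.0) == 0.0

    def test_direct_formula_value(self):
        a = np.zeros(1)
        p = np.array([1.0])  # |a-p|^2 = 1
        n = np.array([0.5])  # |a-n|^2 = 0.25
        assert triplet_loss(a, p, n, margin=1.0) == pytest.approx(1.75)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros(3), np.zeros(2), np.zeros(3), 1.0)


def three_clusters(rng, n_per=20, dim=10, sep=6.0):
    X, y = [], []
    for i, lab in enumerate(["ST", "RSPV", "RSHV"]):
        center = np.zeros(dim)
        center[i] = sep
        X.append(center + rng.normal(0, 1.0, size=(n_per, dim)))
        y += [lab] * n_per
    return np.vstack(X), np.array(y)


class TestTripletEncoder:
    def test_separated_clusters_embed_separably(self):
        rng = np.random.default_rng(0)
        X, y = three_clusters(rng)
        enc = train_triplet_encoder(X, y, TripletEncoderConfig(seed=1, max_epochs=60))
        Z = enc.transform(X)
        within, between = [], []
        for i in range(len(y)):
            for j in range(i + 1, len(y)):
                d = np.linalg.norm(Z[i] - Z[j])
                (within if y[i] == y[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_same_seed_identical_embeddings(self):
        rng = np.random.default_rng(1)
        X, y = three_clusters(rng, n_per=10)
        cfg = TripletEncoderConfig(seed=3, max_epochs=20)
        Z1 = train_triplet_encoder(X, y, cfg).transform(X)
        Z2 = train_triplet_encoder(X, y, cfg).transform(X)
        assert (Z1 == Z2).all()

    def test_training_reduces_mined_loss(self):
        rng = np.random.default_rng(2)
        X, y = three_clusters(rng, sep=3.0)
        enc = train_triplet_encoder(X, y, TripletEncoderConfig(seed=5, max_epochs=80))
        assert enc.loss_history_[-1] < enc.loss_history_[0]

    def test_embedding_dimension_is_64(self):
        rng = np.random.default_rng(3)
        X, y = three_clusters(rng, n_per=8)
        enc = train_triplet_encoder(X, y, TripletEncoderConfig(seed=0, max_epochs=5))
        assert enc.transform(X).shape == (len(y), 64)

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(4).normal(size=(5, 6))
        y = np.array(["ST", "ST", "ST", "ST", "RSPV"])
        with pytest.raises(DataError):
            train_triplet_encoder(X, y, TripletEncoderConfig(seed=0))


class TestReferenceSelection:
    def test_single_cluster_one_reference(self):
        emb = np.zeros((7, 64))  # identical points -> one occupied cell
        refs = select_reference_points(emb, [ScanLocation.ST] * 7, seed=0)
        assert len(refs) == 1

    def test_cardinality_bounded_by_grid(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(150, 64))
        labels = [ScanLocation.ST] * 50 + [ScanLocation.RSPV] * 50 + [ScanLocation.RSHV] * 50
        refs = select_reference_points(emb, labels, grid_rows=10, grid_cols=10, seed=1)
        assert len(refs) <= 100

    def test_one_reference_per_occupied_cell(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(60, 64))
        labels = [ScanLocation.ST] * 60
        refs = select_reference_points(emb, labels, seed=2)
        cells = [e.cell for e in refs.entries]
        assert len(cells) == len(set(cells))
        # recompute each entry's cell from the stored bounds: must agree
        for e in refs.entries:
            assert _grid_cell(np.array(e.tsne_xy), refs.bounds, *refs.grid) == e.cell

    def test_roundtrip_serialization(self, tmp_path):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(30, 64))
        labels = [ScanLocation.ST] * 10 + [ScanLocation.RSPV] * 10 + [ScanLocation.RSHV] * 10
        refs = select_reference_points(emb, labels, seed=3)
        write_reference_set(refs, tmp_path / "refs.h5")
        back = read_reference_set(tmp_path / "refs.h5")
        assert len(back) == len(refs)
        assert back.grid == refs.grid
        assert back.labels == refs.labels
        assert back.embeddings == pytest.approx(refs.embeddings, abs=1e-6)

    def test_summary_has_one_row_per_reference(self):
        rng = np.random.default_rng(3)
        refs = select_reference_points(rng.normal(size=(20, 64)), [ScanLocation.ST] * 20, seed=0)
        assert len(reference_set_summary(refs)) == len(refs)


def brute_force_knn(query, refs, k):
    dists = [float(np.linalg.norm(e.embedding - query)) for e in refs.entries]
    order = sorted(range(len(dists)), key=lambda i: (dists[i], i))[:k]
    votes = {}
    for i in order:
        votes.setdefault(refs.entries[i].label, []).append(i)
    best = max(len(v) for v in votes.values())
    winners = [lab for lab, v in votes.items() if len(v) == best]
    return winners[0] if len(winners) == 1 else refs.entries[order[0]].label


class TestKnnClassify:
    def test_unanimous_references(self):
        rng = np.random.default_rng(0)
        refs = select_reference_points(rng.normal(size=(12, 8)), [ScanLocation.ST] * 12, seed=0)
        assert knn_classify(rng.normal(size=8), refs, k=3) is ScanLocation.ST

    def test_majority_two_of_three(self):
        # construct references with known distances to the origin query
        from liverscan.ambiguity import ReferenceEntry, ReferenceSet

        entries = [
            ReferenceEntry(np.array([1.0, 0.0]), ScanLocation.ST, (0.0, 0.0), (0, 0)),
            ReferenceEntry(np.array([0.0, 1.1]), ScanLocation.ST, (0.0, 0.0), (0, 1)),
            ReferenceEntry(np.array([1.2, 1.2]), ScanLocation.RSPV, (0.0, 0.0), (0, 2)),
            ReferenceEntry(np.array([9.0, 9.0]), ScanLocation.RSHV, (0.0, 0.0), (0, 3)),
        ]
        refs = ReferenceSet(entries, grid=(1, 4), bounds=(0, 3, 0, 0), seed=0)
        assert knn_classify(np.zeros(2), refs, k=3) is ScanLocation.ST

    def test_three_distinct_votes_fall_to_nearest(self):
        from liverscan.ambiguity import ReferenceEntry, ReferenceSet

        entries = [
            ReferenceEntry(np.array([1.0, 0.0]), ScanLocation.RSPV, (0.0, 0.0), (0, 0)),
            ReferenceEntry(np.array([0.0, 2.0]), ScanLocation.ST, (0.0, 0.0), (0, 1)),
            ReferenceEntry(np.array([3.0, 0.0]), ScanLocation.RSHV, (0.0, 0.0), (0, 2)),
        ]
        refs = ReferenceSet(entries, grid=(1, 3), bounds=(0, 2, 0, 0), seed=0)
        assert knn_classify(np.zeros(2), refs, k=3) is ScanLocation.RSPV

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_search(self, seed):
        from liverscan.ambiguity import ReferenceEntry, ReferenceSet

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        # quantized coordinates make distance ties likely, exercising the
        # insertion-order tie rule
        emb = rng.integers(-2, 3, size=(n, 6)).astype(float)
        entries = [
            ReferenceEntry(
                emb[i],
                ScanLocation(rng.choice(["ST", "RSPV", "RSHV"])),
                (0.0, 0.0),
                (i // 5, i % 5),
            )
            for i in range(n)
        ]
        refs = ReferenceSet(entries, grid=(5, 5), bounds=(0, 1, 0, 1), seed=seed)
        query = rng.integers(-2, 3, size=6).astype(float)
        k = int(rng.integers(1, min(4, len(refs) + 1)))
        assert knn_classify(query, refs, k=k) is brute_force_knn(query, refs, k)

    def test_too_few_references_rejected(self):
        rng = np.random.default_rng(1)
        refs = select_reference_points(np.zeros((3, 4)), [ScanLocation.ST] * 3, seed=0)
        with pytest.raises(ConfigurationError):
            knn_classify(rng.normal(size=4), refs, k=len(refs) + 1)
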