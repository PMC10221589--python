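"""Geometric descriptors against independent brute-force oracles.

The oracle recomputes centroid, area fraction and covariance
eigenstructure with explicit loops and the closed-form 2x2
eigendecomposition, fully independently of the implementation.
"""

import math

import numpy as np
import pytest

from liverscan import (
    BinaryMask,
    ScanLocation,
    assemble_feature_vector,
    centroid,
    class_tag,
    geometric_feature_matrix,
    global_average_pool,
    morphology,
    size_fraction,
)
from liverscan.geometry import ConfigurationError, DegenerateMaskError
from liverscan.segmentation_io import ValidationError

from conftest import random_mask


# ---------------------------------------------------------------------
# independent oracle: loops + closed-form 2x2 eigendecomposition
# ---------------------------------------------------------------------


def oracle_stats(mask: BinaryMask):
    pts = sorted(mask.pixels)
    n = len(pts)
    cx = sum(p[0] for p in pts) / n
    cy = sum(p[1] for p in pts) / n
    sxx = sum((p[0] - cx) ** 2 for p in pts) / n
    syy = sum((p[1] - cy) ** 2 for p in pts) / n
    sxy = sum((p[0] - cx) * (p[1] - cy) for p in pts) / n
    # closed-form eigenvalues of [[sxx, sxy], [sxy, syy]]
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc

    def eigvec(lam):
        if abs(sxy) > 1e-12:
            v = (lam - syy, sxy)
        elif sxx >= syy:
            v = (1.0, 0.0) if abs(lam - sxx) < abs(lam - syy) else (0.0, 1.0)
        else:
            v = (0.0, 1.0) if abs(lam - syy) < abs(lam - sxx) else (1.0, 0.0)
        norm = math.hypot(*v)
        v = (v[0] / norm, v[1] / norm)
        # sign: largest-magnitude component positive, ties -> first positive
        idx = 0 if abs(v[0]) >= abs(v[1]) else 1
        if v[idx] < 0:
            v = (-v[0], -v[1])
        return v

    return (cx, cy), n / (mask.height * mask.width), (lam1, lam2), (eigvec(lam1), eigvec(lam2))


class TestGlobalAveragePool:
    def test_constant_channel(self):
        fm = np.full((2, 3, 5), 5.0)
        assert global_average_pool(fm) == pytest.approx([5.0, 5.0])

    def test_ramp_channel_mean(self):
        fm = np.arange(12, dtype=float).reshape(1, 3, 4)
        assert global_average_pool(fm)[0] == pytest.approx(5.5)

    def test_zero_map(self):
        assert (global_average_pool(np.zeros((4, 2, 2))) == 0).all()

    def test_empty_spatial_extent_rejected(self):
        with pytest.raises(ValidationError):
            global_average_pool(np.zeros((3, 0, 4)))


class TestComponents:
    def test_tag(self):
        empty = BinaryMask(frozenset(), 4, 4)
        assert class_tag(empty) == 0
        assert class_tag(BinaryMask(frozenset({(1, 1)}), 4, 4)) == 1

    def test_centroid_examples(self):
        assert centroid(BinaryMask(frozenset({(0, 0), (2, 0)}), 4, 4)) == (1.0, 0.0)
        assert centroid(BinaryMask(frozenset({(3, 5)}), 8, 8)) == (3.0, 5.0)
        full = BinaryMask(frozenset((x, y) for x in range(4) for y in range(4)), 4, 4)
        assert centroid(full) == (1.5, 1.5)

    def test_centroid_empty_mask_errors(self):
        with pytest.raises(DegenerateMaskError):
            centroid(BinaryMask(frozenset(), 4, 4))

    def test_size_fraction_examples(self):
        assert size_fraction(BinaryMask(frozenset(), 4, 4)) == 0.0
        eight = BinaryMask(frozenset((x, 0) for x in range(4)) | frozenset((x, 1) for x in range(4)), 4, 4)
        assert size_fraction(eight) == 0.5

    def test_morphology_single_pixel_degenerate(self):
        m = morphology(BinaryMask(frozenset({(2, 2)}), 5, 5))
        assert m == pytest.approx([0, 0, 1, 0, 0, 1])

    def test_morphology_horizontal_line(self):
        mask = BinaryMask(frozenset((x, 0) for x in range(5)), 1, 5)
        lam1, lam2, v1x, v1y, *_ = morphology(mask)
        assert lam2 == pytest.approx(0.0, abs=1e-12)
        assert (v1x, v1y) == pytest.approx((1.0, 0.0))

    def test_morphology_solid_square_tie_rule(self):
        mask = BinaryMask(frozenset((x, y) for x in range(3) for y in range(3)), 3, 3)
        lam1, lam2, v1x, v1y, v2x, v2y = morphology(mask)
        assert lam1 == pytest.approx(lam2)
        assert (v1x, v1y, v2x, v2y) == pytest.approx((1, 0, 0, 1))


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(200))
    def test_centroid_size_morphology_match_bruteforce(self, seed):
        mask = random_mask(np.random.default_rng(seed))
        (ocx, ocy), osize, (ol1, ol2), (ov1, ov2) = oracle_stats(mask)
        assert centroid(mask) == pytest.approx((ocx, ocy), abs=1e-9)
        assert size_fraction(mask) == pytest.approx(osize, abs=1e-9)
        lam1, lam2, v1x, v1y, v2x, v2y = morphology(mask)
        assert (lam1, lam2) == pytest.approx((ol1, ol2), abs=1e-9)
        if not np.isclose(ol1, ol2):  # non-degenerate: eigenvectors defined
            assert (v1x, v1y) == pytest.approx(ov1, abs=1e-7)
            assert (v2x, v2y) == pytest.approx(ov2, abs=1e-7)

    @pytest.mark.parametrize("seed", range(20))
    def test_eigenvectors_orthonormal(self, seed):
        mask = random_mask(np.random.default_rng(seed + 1000))
        if len({p for p in mask.pixels}) < 2:
            pytest.skip("needs >= 2 distinct pixels")
        _, _, v1x, v1y, v2x, v2y = morphology(mask)
        v1, v2 = np.array([v1x, v1y]), np.array([v2x, v2y])
        assert np.linalg.norm(v1) == pytest.approx(1.0)
        assert np.linalg.norm(v2) == pytest.approx(1.0)
        assert abs(v1 @ v2) == pytest.approx(0.0, abs=1e-9)


class TestGeometricFeatureMatrix:
    def test_shape_and_zero_rows_for_undetected(self):
        cm = np.zeros((8, 8), int)
        cm[2:5, 2:5] = 1
        gf = geometric_feature_matrix(cm, 4)
        assert gf.matrix.shape == (3, 10)
        assert gf.matrix[0, 0] == 1.0
        assert (gf.matrix[1] == 0).all() and (gf.matrix[2] == 0).all()

    def test_all_background_gives_zero_matrix(self):
        assert (geometric_feature_matrix(np.zeros((6, 6), int), 5).matrix == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_rows_equal_componentwise_oracles(self, seed):
        from liverscan import binary_masks

        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 4, size=(9, 9))
        gf = geometric_feature_matrix(cm, 4)
        for i, mask in enumerate(binary_masks(cm, 4)):
            row = gf.matrix[i]
            if len(mask) == 0:
                assert (row == 0).all()
                continue
            (ocx, ocy), osize, (ol1, ol2), _ = oracle_stats(mask)
            assert row[0] == 1.0
            assert row[1:4] == pytest.approx([ocx, ocy, osize], abs=1e-9)
            assert row[4:6] == pytest.approx([ol1, ol2], abs=1e-9)

    @pytest.mark.parametrize("dx,dy", [(2, 0), (0, 3), (1, 1)])
    def test_translation_covariance(self, dx, dy):
        cm = np.zeros((16, 16), int)
        cm[3:7, 2:8] = 1
        shifted = np.zeros((16, 16), int)
        shifted[3 + dy : 7 + dy, 2 + dx : 8 + dx] = 1
        a = geometric_feature_matrix(cm, 2).matrix[0]
        b = geometric_feature_matrix(shifted, 2).matrix[0]
        assert b[1] - a[1] == pytest.approx(dx)
        assert b[2] - a[2] == pytest.approx(dy)
        assert b[0] == a[0]
        assert b[3] == pytest.approx(a[3])  # size: same pixel count, same raster
        assert b[4:] == pytest.approx(a[4:])


class TestAssembleFeatureVector:
    def test_geometric_only_length(self, small_dataset):
        art = small_dataset[0].organ
        fv = assemble_feature_vector(art, parts=("geometric",))
        assert fv.values.shape == ((art.n_classes - 1) * 10,)

    def test_all_parts_length_is_sum_of_segments(self, small_dataset):
        art = small_dataset[0].organ
        fv = assemble_feature_vector(art)
        c_f = art.feature_map.shape[0]
        c_q = art.query_embeddings.shape[0]
        n = art.n_classes
        assert fv.values.shape[0] == c_f + c_q * n + n * (n + 1) + (n - 1) * 10
        assert fv.offsets["gap"] == (0, c_f)

    def test_deterministic(self, small_dataset):
        art = small_dataset[0].organ
        a = assemble_feature_vector(art).values
        b = assemble_feature_vector(art).values
        assert (a == b).all()

    def test_missing_part_named_in_error(self, small_dataset):
        art = small_dataset[0].organ
        import dataclasses

        bare = dataclasses.replace(art, feature_map=None)
        with pytest.raises(ConfigurationError, match="gap"):
            assemble_feature_vector(bare, parts=("gap",))
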