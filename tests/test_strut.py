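"""Strut pixel classification, counts and the fourteen ratio features."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from trabeculex import (
    BinaryImage,
    SkeletonImage,
    TrabecularParams,
    classify_pixels,
    generate_trabecular_roi,
    run_chain,
    strut_metrics,
    strut_ratios,
)
from trabeculex.strut import RATIO_NAMES, StrutFeatures
from .conftest import random_blob_mask


def _sk(mask):
    return SkeletonImage(mask, 0.1)


def _bin(mask):
    return BinaryImage(mask, 0.1)


def brute_force_counts(mask: np.ndarray, skeleton: np.ndarray) -> dict:
    """Independent per-pixel re-scan oracle for the strut counts."""
    h, w = mask.shape
    hda = periphery = tsl = n_tm = 0
    node = np.zeros_like(skeleton)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                hda += 1
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        periphery += 1
                        break
            if skeleton[r, c]:
                tsl += 1
                nb = 0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and skeleton[rr, cc]:
                            nb += 1
                if nb == 1:
                    n_tm += 1
                elif nb >= 3:
                    node[r, c] = True
    n_nd = ndi.label(node, ndi.generate_binary_structure(2, 1))[1]
    return {"hda": hda, "periphery": periphery, "tsl": tsl, "n_tm": n_tm, "n_nd": n_nd}


class TestClassifyPixels:
    def test_plus_sign(self):
        # plus sign with arm length 2: the tips are termini; the centre and
        # arm-mid pixels all have >= 3 8-neighbours (diagonal contacts) and
        # form a single 4-connected node cluster — one crossing point
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 1:6] = True
        mask[1:6, 3] = True
        classes = classify_pixels(_sk(mask))
        assert classes.n_node_clusters == 1
        assert classes.n_terminus == 4
        assert classes.node[3, 3]

    def test_straight_line(self):
        mask = np.zeros((3, 7), dtype=bool)
        mask[1, 1:6] = True
        classes = classify_pixels(_sk(mask))
        assert classes.n_terminus == 2
        assert int(classes.strut.sum()) == 3
        assert classes.n_node_clusters == 0

    def test_single_pixel_is_isolated(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        classes = classify_pixels(_sk(mask))
        assert int(classes.isolated.sum()) == 1
        assert classes.n_terminus == 0
        assert classes.n_node_clusters == 0

    def test_classes_partition_the_skeleton(self, rng):
        mask = random_blob_mask(rng, shape=(40, 40))
        from trabeculex import skeletonize

        sk = skeletonize(_bin(mask))
        classes = classify_pixels(sk)
        union = classes.terminus | classes.strut | classes.node | classes.isolated
        assert np.array_equal(union, sk.mask)
        total = (classes.terminus.sum() + classes.strut.sum()
                 + classes.node.sum() + classes.isolated.sum())
        assert total == sk.mask.sum()


class TestStrutMetrics:
    def test_2x2_block_all_periphery(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True
        feats = strut_metrics(_bin(mask), _sk(np.zeros((10, 10), dtype=bool)))
        assert feats.hda_px == 4
        assert feats.periphery_px == 4

    def test_4x4_block_interior_excluded(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 3:7] = True
        feats = strut_metrics(_bin(mask), _sk(np.zeros((10, 10), dtype=bool)))
        assert feats.hda_px == 16
        assert feats.periphery_px == 12

    def test_border_counts_as_background(self):
        mask = np.ones((4, 4), dtype=bool)
        feats = strut_metrics(_bin(mask), _sk(np.zeros((4, 4), dtype=bool)))
        assert feats.periphery_px == 12  # 16 minus the 4 interior pixels

    def test_empty_mask_gives_zero_counts(self):
        empty = np.zeros((8, 8), dtype=bool)
        feats = strut_metrics(_bin(empty), _sk(empty))
        assert (feats.hda_px, feats.periphery_px, feats.tsl_px,
                feats.n_tm, feats.n_nd) == (0, 0, 0.0, 0, 0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            strut_metrics(_bin(np.zeros((5, 5), dtype=bool)),
                          _sk(np.zeros((6, 5), dtype=bool)))

    def test_matches_brute_force_oracle(self, rng):
        from trabeculex import skeletonize

        for _ in range(40):
            shape = (int(rng.integers(8, 33)), int(rng.integers(8, 33)))
            mask = random_blob_mask(rng, shape=shape, smooth=1.5)
            sk = skeletonize(_bin(mask))
            feats = strut_metrics(_bin(mask), sk)
            oracle = brute_force_counts(mask, sk.mask)
            assert feats.hda_px == oracle["hda"]
            assert feats.periphery_px == oracle["periphery"]
            assert feats.tsl_px == oracle["tsl"]
            assert feats.n_tm == oracle["n_tm"]
            assert feats.n_nd == oracle["n_nd"]

    def test_weighted_tsl_counts_diagonals(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[np.arange(4), np.arange(4)] = True  # 4-pixel diagonal
        feats = strut_metrics(_bin(mask), _sk(mask), tsl_weighted=True)
        assert feats.tsl_px == pytest.approx(3 * np.sqrt(2))

    def test_node_pixel_mode_counts_pixels(self):
        # two diagonally-touching plus signs merged: cluster vs pixel counting
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 1:6] = True
        mask[1:6, 3] = True
        mask[2, 2] = True
        cluster = strut_metrics(_bin(mask), _sk(mask), node_mode="cluster")
        pixel = strut_metrics(_bin(mask), _sk(mask), node_mode="pixel")
        assert pixel.n_nd >= cluster.n_nd


class TestStrutRatios:
    def test_basic_ratio(self):
        feats = StrutFeatures(total_area_px=100, hda_px=50, periphery_px=20,
                              tsl_px=10.0, n_tm=4, n_nd=2, pixel_size_mm=0.1)
        ratios = strut_ratios(feats)
        assert ratios["hda/total_area"] == pytest.approx(0.5)
        assert set(ratios) == set(RATIO_NAMES)

    def test_terminus_per_length_arithmetic(self):
        feats = StrutFeatures(total_area_px=25, hda_px=5, periphery_px=5,
                              tsl_px=5.0, n_tm=4, n_nd=1, pixel_size_mm=0.1)
        assert strut_ratios(feats)["n_tm/tsl"] == pytest.approx(4 / 5)

    def test_plus_sign_counts(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 1:6] = True
        mask[1:6, 3] = True
        feats = strut_metrics(_bin(mask), _sk(mask))
        ratios = strut_ratios(feats)
        assert feats.n_nd == 1 and feats.n_tm == 4
        assert ratios["n_tm/tsl"] == pytest.approx(4 / 9)

    def test_zero_denominator_is_nan(self):
        feats = StrutFeatures(total_area_px=100, hda_px=50, periphery_px=20,
                              tsl_px=10.0, n_tm=0, n_nd=2, pixel_size_mm=0.1)
        assert np.isnan(strut_ratios(feats)["n_nd/n_tm"])

    def test_zero_total_area_raises(self):
        feats = StrutFeatures(total_area_px=0, hda_px=0, periphery_px=0,
                              tsl_px=0.0, n_tm=0, n_nd=0, pixel_size_mm=0.1)
        with pytest.raises(ValueError):
            strut_ratios(feats)

    def test_per_cm2_uses_pixel_size(self):
        feats = StrutFeatures(total_area_px=2500, hda_px=100, periphery_px=10,
                              tsl_px=10.0, n_tm=5, n_nd=2, pixel_size_mm=0.1)
        # 2500 px at 0.1 mm = 25 mm^2 = 0.25 cm^2
        assert strut_ratios(feats)["n_tm/cm2"] == pytest.approx(5 / 0.25)


class TestParameterResponse:
    def test_hda_fraction_increases_with_bone_fraction(self):
        values = []
        for bf in (0.3, 0.45, 0.6):
            params = TrabecularParams(bone_fraction=bf, noise_sd=0.0,
                                      gradient_amplitude=0.0, seed=4)
            img, _ = generate_trabecular_roi(params)
            result = run_chain(img)
            feats = strut_metrics(result.binary, result.skeleton)
            values.append(strut_ratios(feats)["hda/total_area"])
        assert values[0] < values[1] < values[2]

    def test_hda_fraction_robust_to_resolution(self):
        # a smooth mask sampled on a 2x finer grid keeps its area fraction:
        # pixel counting only accrues error along the boundary
        def smooth_mask(n):
            y, x = np.mgrid[0:n, 0:n] / n
            return ((x - 0.4) ** 2 + (y - 0.5) ** 2 < 0.08) | \
                   ((x - 0.7) ** 2 + (y - 0.3) ** 2 < 0.03)

        fractions = []
        for n in (64, 128):
            mask = smooth_mask(n)
            empty = np.zeros_like(mask)
            feats = strut_metrics(_bin(mask), _sk(empty))
            fractions.append(strut_ratios(feats)["hda/total_area"])
        assert abs(fractions[0] - fractions[1]) <= 0.02
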