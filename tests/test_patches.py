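"""Patch taxonomy, index, augmentation and balanced sampling."""

import numpy as np
import pytest
from scipy import stats

from mcseg.patches import (
    PATCH_CLASSES,
    PatchRecord,
    augment,
    build_patch_index,
    classify_all_centers,
    classify_patch,
    extract_window,
    sample_minibatch,
)
from mcseg.phantom import Mammogram, MCMask

from conftest import brute_force_patch_class


def _window(n=49, ones=()):
    w = np.zeros((n, n), dtype=np.uint8)
    for r, c in ones:
        w[r, c] = 1
    return w


class TestClassifyPatch:
    def test_empty_window_is_c4(self):
        assert classify_patch(_window(49)) == "C4"

    def test_center_pixel_is_c1(self):
        n = 49
        assert classify_patch(_window(n, [(n // 2, n // 2)])) == "C1"

    def test_near_center_is_c2(self):
        n = 49
        c = n // 2
        assert classify_patch(_window(n, [(c + 2, c)])) == "C2"

    def test_corner_pixel_is_c3(self):
        assert classify_patch(_window(49, [(0, 0)])) == "C3"

    def test_c2_boundary_is_euclidean(self):
        n, c = 21, 10
        assert classify_patch(_window(n, [(c + 3, c)])) == "C2"      # d = 3
        assert classify_patch(_window(n, [(c + 3, c + 1)])) == "C3"  # d = sqrt(10)

    def test_even_side_rejected(self):
        with pytest.raises(ValueError):
            classify_patch(np.zeros((10, 10)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            classify_patch(np.full((9, 9), 2))

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.choice([9, 15, 21]))
            w = (rng.random((n, n)) < 0.02).astype(np.uint8)
            assert classify_patch(w) == brute_force_patch_class(w)


class TestPatchIndex:
    def test_all_background_mask_gives_only_c4(self):
        rng = np.random.default_rng(1)
        image = Mammogram(rng.random((64, 64)))
        mask = MCMask(np.zeros((64, 64), dtype=np.uint8))
        db = build_patch_index(image, mask, 21, np.ones((64, 64), bool))
        counts = db.class_counts()
        assert counts["C4"] == 64 * 64
        assert counts["C1"] == counts["C2"] == counts["C3"] == 0

    def test_single_pixel_mc_gives_one_c1(self):
        image = Mammogram(np.random.default_rng(2).random((64, 64)))
        m = np.zeros((64, 64), dtype=np.uint8)
        m[30, 31] = 1
        db = build_patch_index(image, MCMask(m), 49, np.ones((64, 64), bool))
        recs = db.records(classes=["C1"])
        assert recs == [PatchRecord("image_0000", 30, 31, "C1")]

    def test_no_foreground_rejected(self, small_phantom):
        _, image, mask = small_phantom
        with pytest.raises(ValueError):
            build_patch_index(image, mask, 21, np.zeros(image.shape, bool))

    def test_index_matches_window_reclassification(self, small_phantom, small_db):
        """Stored classes equal brute-force classify_patch of each window."""
        _, _, mask = small_phantom
        recs = small_db.records()
        rng = np.random.default_rng(3)
        for i in rng.choice(len(recs), size=500, replace=False):
            r = recs[i]
            window = extract_window(mask.pixels, r.center_row, r.center_col, 21)
            assert r.patch_class == classify_patch(window)

    def test_classes_partition_eligible_windows(self, small_db):
        counts = small_db.class_counts()
        fg_total = sum(counts.values())
        assert fg_total > 0
        assert set(counts) == set(PATCH_CLASSES)

    def test_label_consistency(self, small_db):
        for rec in small_db.records():
            assert rec.detector_label >= rec.segmentator_label


class TestAugment:
    def test_identity_transform(self):
        rng = np.random.default_rng(4)
        p = rng.random((9, 9))
        out, _ = augment(p, None, 0)
        assert np.array_equal(out, p)

    def test_rotation_has_order_four(self):
        p = np.random.default_rng(5).random((9, 9))
        q = p
        for _ in range(4):
            q, _ = augment(q, None, 1)
        assert np.allclose(q, p)

    def test_image_and_labels_transform_together(self):
        rng = np.random.default_rng(6)
        p = rng.random((9, 9))
        lab = (rng.random((9, 9)) < 0.3).astype(np.uint8)
        for t in range(8):
            tp, tl = augment(p, lab, t)
            # the peak pixel of the image moves exactly with its label value
            idx = np.unravel_index(np.argmax(tp), tp.shape)
            src = np.unravel_index(np.argmax(p), p.shape)
            assert lab[src] == tl[idx]

    def test_patch_class_invariant_under_all_transforms(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            w = (rng.random((15, 15)) < 0.03).astype(np.uint8)
            ref = classify_patch(w)
            for t in range(8):
                _, tw = augment(w.astype(float), w, t)
                assert classify_patch(tw) == ref

    def test_invalid_transform_id(self):
        with pytest.raises(ValueError):
            augment(np.zeros((9, 9)), None, 8)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((9, 11)), None, 1)


class TestSampleMinibatch:
    def test_exact_balance_detector(self, small_db):
        rng = np.random.default_rng(8)
        for _ in range(20):
            mb = sample_minibatch(small_db, "detector", 32, rng)
            pos = sum(k in ("C1", "C2", "C3") for k in mb.patch_classes)
            assert pos == 16
            assert mb.labels.sum(axis=0)[1] == 16

    def test_segmentator_positive_is_c1_only(self, small_db):
        rng = np.random.default_rng(9)
        mb = sample_minibatch(small_db, "segmentator", 16, rng)
        for klass, label in zip(mb.patch_classes, mb.labels):
            assert (label[1] == 1) == (klass == "C1")

    def test_batch_of_two(self, small_db):
        mb = sample_minibatch(small_db, "detector", 2, np.random.default_rng(10))
        assert mb.labels.sum(axis=0).tolist() == [1.0, 1.0]

    def test_same_rng_state_reproduces_batch(self, small_db):
        a = sample_minibatch(small_db, "detector", 32, np.random.default_rng(11))
        b = sample_minibatch(small_db, "detector", 32, np.random.default_rng(11))
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.labels, b.labels)
        assert a.patch_classes == b.patch_classes

    def test_odd_batch_size_rejected(self, small_db):
        with pytest.raises(ValueError):
            sample_minibatch(small_db, "detector", 33, np.random.default_rng(0))

    def test_within_class_sampling_is_uniform(self):
        """Chi-square GoF on positive-pool draw counts, 10^4 draws, alpha 0.01.

        The image holds a distinct intensity at every pixel and the center
        pixel is fixed by every dihedral transform, so each drawn positive
        patch identifies its source record exactly.
        """
        side = 40
        image = Mammogram(np.arange(side * side, dtype=float).reshape(side, side) / (side * side))
        m = np.zeros((side, side), dtype=np.uint8)
        mc_pixels = [(8, 8), (8, 30), (18, 12), (20, 28), (30, 7), (30, 20), (33, 33), (12, 20)]
        for r, c in mc_pixels:
            m[r, c] = 1
        db = build_patch_index(image, MCMask(m), 9, np.ones((side, side), bool))
        norm = db._images["image_0000"][0]
        center_values = {norm[r, c]: i for i, (r, c) in enumerate(mc_pixels)}

        rng = np.random.default_rng(12)
        counts = np.zeros(len(mc_pixels))
        n_batches = 10_000 // 25
        for _ in range(n_batches):
            mb = sample_minibatch(db, "segmentator", 50, rng)
            half = 9 // 2
            for pix, lab in zip(mb.pixels, mb.labels):
                if lab[1] == 1:
                    counts[center_values[pix[0, half, half]]] += 1
        assert counts.sum() == n_batches * 25
        _, p = stats.chisquare(counts)
        assert p > 0.01
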