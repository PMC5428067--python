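"""Segmentation metrics against brute-force oracles; ROC and bootstrap."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from wmgm4d.core import LabelMask
from wmgm4d.evaluation import (
    EvalReport,
    StructureMetrics,
    _auc,
    avd,
    bootstrap_compare,
    dice,
    merged_roc,
    slicewise_evaluate,
    surface_distances,
    _boundary,
)


def brute_force_distances(a, b, spacing):
    """All-pairs oracle for the boundary-distance metrics."""
    pa = np.argwhere(_boundary(a)) * np.asarray(spacing)
    pb = np.argwhere(_boundary(b)) * np.asarray(spacing)
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return {
        "hd": max(d_ab.max(), d_ba.max()),
        "mhd": max(d_ab.mean(), d_ba.mean()),
        "hd95": max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)),
        "cmd": 0.5 * (d_ab.mean() + d_ba.mean()),
    }


def random_blob(rng, shape=(14, 14, 14)):
    """A random nonempty mask: a few overlapping boxes."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        lo = rng.integers(0, 8, size=3)
        hi = lo + rng.integers(2, 6, size=3)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return mask


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:5] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[0], b[5] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros((10, 10, 10), dtype=bool)
        a.flat[:100] = True
        b.flat[50:150] = True
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        e = np.zeros((4, 4, 4), dtype=bool)
        assert dice(e, e) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = random_blob(rng), random_blob(rng)
        assert dice(a, b) == dice(b, a)


class TestAvd:
    def test_equal_volumes(self):
        m = np.ones((5, 5, 4), dtype=bool)
        assert avd(m, m) == 0.0

    def test_fifteen_percent(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros((10, 10, 10), dtype=bool)
        a.flat[:115] = True
        b.flat[:100] = True
        assert avd(a, b) == pytest.approx(15.0)

    def test_empty_prediction(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        b = np.ones((5, 5, 5), dtype=bool)
        assert avd(a, b) == 100.0

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            avd(np.ones((4, 4, 4), dtype=bool), np.zeros((4, 4, 4), dtype=bool))


class TestSurfaceDistances:
    def test_identical_masks_are_zero(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:6, 2:6, 2:6] = True
        sd = surface_distances(m, m)
        assert sd.hd == sd.mhd == sd.hd95 == sd.cmd == 0.0

    def test_single_voxels_three_mm_apart(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros((10, 10, 10), dtype=bool)
        a[2, 5, 5] = True
        b[5, 5, 5] = True
        sd = surface_distances(a, b, spacing=(1.0, 1.0, 1.0))
        assert sd.hd == sd.mhd == sd.hd95 == sd.cmd == pytest.approx(3.0)

    def test_empty_mask_error_names_offender(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        full = np.ones((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError, match="first"):
            surface_distances(m, full)
        with pytest.raises(ValueError, match="second"):
            surface_distances(full, m)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_blob(rng), random_blob(rng)
        spacing = (1.0, 1.0, 1.0)
        sd = surface_distances(a, b, spacing=spacing)
        oracle = brute_force_distances(a, b, spacing)
        for key in oracle:
            assert getattr(sd, key) == pytest.approx(oracle[key], abs=1e-9)

    def test_distances_scale_with_spacing(self):
        rng = np.random.default_rng(5)
        a, b = random_blob(rng), random_blob(rng)
        sd1 = surface_distances(a, b, spacing=(1.0, 1.0, 1.0))
        sd2 = surface_distances(a, b, spacing=(2.0, 2.0, 2.0))
        for key in ("hd", "mhd", "hd95", "cmd"):
            assert getattr(sd2, key) == pytest.approx(2 * getattr(sd1, key))


class TestSlicewise:
    def _mask(self, boxes, shape=(12, 12, 4)):
        m = np.zeros(shape, dtype=bool)
        for z, (lo, hi) in boxes.items():
            m[lo:hi, lo:hi, z] = True
        return LabelMask(m)

    def test_single_slice_aggregation_is_identity(self):
        seg = self._mask({1: (2, 6)})
        ref = self._mask({1: (3, 7)})
        out = slicewise_evaluate(seg, ref)
        sd = surface_distances(seg.data[:, :, 1], ref.data[:, :, 1], spacing=(1.0, 1.0))
        assert out.DC == pytest.approx(dice(seg.data[:, :, 1], ref.data[:, :, 1]))
        assert out.HD == pytest.approx(sd.hd)
        assert out.n_slices == 1

    def test_mean_and_max_aggregation(self):
        seg = self._mask({0: (2, 6), 2: (2, 6)})
        ref = self._mask({0: (2, 6), 2: (4, 8)})
        out = slicewise_evaluate(seg, ref)
        dc0 = dice(seg.data[:, :, 0], ref.data[:, :, 0])  # 1.0
        dc2 = dice(seg.data[:, :, 2], ref.data[:, :, 2])
        assert out.DC == pytest.approx((dc0 + dc2) / 2)
        hd2 = surface_distances(seg.data[:, :, 2], ref.data[:, :, 2], spacing=(1.0, 1.0)).hd
        assert out.HD == pytest.approx(max(0.0, hd2))
        assert out.n_slices == 2

    def test_empty_slices_skipped(self):
        seg = self._mask({1: (2, 6), 3: (2, 6)})
        ref = self._mask({1: (2, 6)})  # slice 3 empty in the reference
        out = slicewise_evaluate(seg, ref)
        assert out.n_slices == 1

    def test_no_overlapping_slices_is_an_error(self):
        seg = self._mask({0: (2, 6)})
        ref = self._mask({2: (2, 6)})
        with pytest.raises(ValueError, match="no slice"):
            slicewise_evaluate(seg, ref)


class TestRoc:
    def test_perfect_probabilities(self):
        labels = np.repeat([0, 1], 50)
        roc = merged_roc([labels.astype(float)], [labels])
        assert roc.az == pytest.approx(1.0)

    def test_random_probabilities_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 20_000)
        scores = rng.uniform(0, 1, 20_000)
        roc = merged_roc([scores], [labels])
        assert roc.az == pytest.approx(0.5, abs=0.02)

    def test_pooling_equals_concatenation(self):
        rng = np.random.default_rng(1)
        scores = [rng.uniform(0, 1, 100) for _ in range(3)]
        labels = [rng.integers(0, 2, 100) for _ in range(3)]
        pooled = merged_roc(scores, labels)
        direct = merged_roc([np.concatenate(scores)], [np.concatenate(labels)])
        assert pooled.az == pytest.approx(direct.az)

    def test_single_class_pool_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            merged_roc([np.array([0.1, 0.9])], [np.array([1, 1])])

    def test_rank_auc_matches_sklearn(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 500)
        scores = rng.normal(size=500) + labels
        assert _auc(labels, scores) == pytest.approx(roc_auc_score(labels, scores))


class TestBootstrap:
    def test_identical_inputs_not_significant(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 400)
        scores = rng.normal(size=400) + 0.8 * labels
        out = bootstrap_compare(scores, labels, scores, labels, n_boot=1000, seed=1)
        assert out.p_value > 0.9
        assert out.ci_a == out.ci_b

    def test_ci_shrinks_with_more_data(self):
        rng = np.random.default_rng(3)
        def make(n):
            labels = rng.integers(0, 2, n)
            return rng.normal(size=n) + labels, labels
        s_small, l_small = make(300)
        s_big, l_big = make(3000)
        small = bootstrap_compare(s_small, l_small, s_small, l_small, n_boot=1000, seed=0)
        big = bootstrap_compare(s_big, l_big, s_big, l_big, n_boot=1000, seed=0)
        assert (big.ci_a[1] - big.ci_a[0]) < (small.ci_a[1] - small.ci_a[0])

    def test_clear_difference_detected(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 600)
        good = rng.normal(size=600) + 2.0 * labels
        bad = rng.normal(size=600) + 0.1 * labels
        out = bootstrap_compare(good, labels, bad, labels, n_boot=1000, seed=0)
        assert out.az_a > out.az_b
        assert out.p_value < 0.01

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare(np.zeros(4), np.array([0, 1, 0, 1]),
                              np.zeros(4), np.array([0, 1, 0, 1]), n_boot=10)


class TestEvalReport:
    def test_summary_mean_and_std_over_folds(self):
        report = EvalReport()
        m1 = StructureMetrics(DC=0.8, AVD=10.0, HD=5.0, MHD=1.0, HD95=3.0, CMD=0.5, n_slices=4)
        m2 = StructureMetrics(DC=0.6, AVD=20.0, HD=7.0, MHD=2.0, HD95=5.0, CMD=1.5, n_slices=4)
        report.add("f1", "WM", m1)
        report.add("f2", "WM", m2)
        s = report.summary()
        assert s.loc["WM", "DC_mean"] == pytest.approx(0.7)
        assert s.loc["WM", "DC_std"] == pytest.approx(np.std([0.8, 0.6], ddof=1))
        table = report.to_table()
        assert "±" in table.loc["WM", "DC"]
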