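"""Metric and statistics unit tests, checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from mskseg.evaluate import aie, asd, ave, ccc, compare_groups, dice, agreement
from conftest import random_mask


def brute_force_dice(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def brute_force_boundary(mask):
    """Independent 6-neighbourhood boundary extraction (loop-based)."""
    m = np.asarray(mask, bool)
    out = np.zeros_like(m)
    padded = np.pad(m, 1)
    for k, i, j in zip(*np.nonzero(m)):
        nb = [
            padded[k, i + 1, j + 1], padded[k + 2, i + 1, j + 1],
            padded[k + 1, i, j + 1], padded[k + 1, i + 2, j + 1],
            padded[k + 1, i + 1, j], padded[k + 1, i + 1, j + 2],
        ]
        if not all(nb):
            out[k, i, j] = True
    return out


def brute_force_asd(a, b, spacing):
    sa = np.argwhere(brute_force_boundary(a)) * np.asarray(spacing)
    sb = np.argwhere(brute_force_boundary(b)) * np.asarray(spacing)
    d = cdist(sa, sb)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sb))


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3, 1:3, 1:3] = True
        assert dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[0, 0, 0] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((2, 2, 4), bool)
        b = np.zeros_like(a)
        a[0, 0, :4] = True  # |A| = 4
        b[0, 1, :2] = b[0, 0, :2] = True  # |B| = 4, overlap 2
        assert dice(a, b) == 0.5

    def test_both_empty_is_vacuous_one(self):
        e = np.zeros((3, 3, 3), bool)
        with pytest.warns(UserWarning):
            assert dice(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))

    def test_symmetry_random(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = random_mask(rng), random_mask(rng)
            assert dice(a, b) == dice(b, a) == pytest.approx(brute_force_dice(a, b))


class TestAsd:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert asd(m, m, (1, 1, 1)) == 0.0

    def test_single_voxel_pair(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros_like(a)
        a[4, 4, 2] = True
        b[4, 4, 5] = True
        assert asd(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_empty_mask_raises(self):
        m = np.zeros((4, 4, 4), bool)
        f = m.copy()
        f[1, 1, 1] = True
        with pytest.raises(ValueError):
            asd(m, f, (1, 1, 1))

    def test_anisotropic_spacing(self):
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros_like(a)
        a[2, 2, 2] = True
        b[4, 2, 2] = True  # 2 slices apart at 6 mm each
        assert asd(a, b, (6.0, 0.7, 0.7)) == pytest.approx(12.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            a, b = random_mask(rng), random_mask(rng)
            if not (a.any() and b.any()):
                continue
            sp = tuple(rng.uniform(0.5, 3.0, 3))
            assert asd(a, b, sp) == pytest.approx(brute_force_asd(a, b, sp), abs=1e-9)
            assert asd(a, b, sp) == pytest.approx(asd(b, a, sp))


class TestVolumeIntensityErrors:
    @pytest.mark.parametrize("gt,pred,expected", [(100, 100, 0.0), (100, 95, 5.0), (50, 60, 20.0)])
    def test_ave(self, gt, pred, expected):
        assert ave(gt, pred) == pytest.approx(expected)

    def test_ave_zero_gt_raises(self):
        with pytest.raises(ValueError):
            ave(0.0, 5.0)

    @pytest.mark.parametrize("gt,pred,expected", [(20, 20, 0.0), (30, 28, 2.0), (45.6, 46.15, 0.55)])
    def test_aie(self, gt, pred, expected):
        assert aie(gt, pred) == pytest.approx(expected)


class TestCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert ccc(x, x) == pytest.approx(1.0)

    def test_shifted_line(self):
        # cov = 2/3, vars = 2/3 each, mean shift 1 -> 2*(2/3)/(4/3+1) = 4/7
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_anticorrelated_bounded(self):
        x = np.array([1.0, 2.0, 3.0])
        v = ccc(x, -x)
        assert -1.0 <= v < 0.0

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_ccc_never_exceeds_pearson(self, xs, seed):
        x = np.asarray(xs)
        rng = np.random.default_rng(seed)
        y = x * rng.uniform(-2, 2) + rng.normal(0, 5, x.size)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        s = agreement(x, y)
        assert abs(s.ccc) <= abs(s.pearson_rho) + 1e-12


class TestCompareGroups:
    def test_bonferroni_alpha_three_comparisons(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 20), rng.normal(0, 1, 20), n_comparisons=3)
        assert res.adjusted_alpha == pytest.approx(0.05 / 3)
        assert round(res.adjusted_alpha, 4) == 0.0167

    def test_identical_vectors_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning):
            res = compare_groups(a, a.copy(), paired=True)
        assert not res.significant
        assert res.raw_p == 1.0

    def test_selects_wilcoxon_for_skewed_data(self):
        rng = np.random.default_rng(3)
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.0, 40) ** 3
        res = compare_groups(a, b, paired=True)
        assert res.test_name == "wilcoxon"

    def test_selects_t_test_for_normal_data(self):
        rng = np.random.default_rng(4)
        res = compare_groups(rng.normal(0, 1, 30), rng.normal(0, 1, 30), paired=True)
        assert res.test_name == "t_test"

    def test_unpaired_mode_labeled_distinctly(self):
        rng = np.random.default_rng(5)
        a = rng.exponential(1.0, 30) ** 3
        b = rng.exponential(1.0, 25) ** 3
        res = compare_groups(a, b, paired=False)
        assert res.test_name in ("t_test", "wilcoxon_rank_sum")


def test_degradation_monotonicity():
    """Eroding the prediction strictly lowers DC and raises ASD."""
    from scipy import ndimage

    gt = np.zeros((24, 24, 24), bool)
    zz, yy, xx = np.ogrid[:24, :24, :24]
    gt[((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 81] = True
    dcs, asds = [], []
    pred = gt.copy()
    for _ in range(3):
        dcs.append(dice(gt, pred))
        asds.append(asd(gt, pred, (1, 1, 1)))
        pred = ndimage.binary_erosion(pred)
    assert dcs[0] > dcs[1] > dcs[2]
    assert asds[0] < asds[1] < asds[2]
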