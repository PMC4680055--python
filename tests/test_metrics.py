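import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainsegeval.metrics import (
    BoundaryPointSet,
    UndefinedMetricError,
    avd,
    dice,
    directed_h95,
    extract_boundary,
    h95,
    mask_metrics,
    wml_sensitivity,
)
from brainsegeval.volumes import Component, LabelVolume, Scheme

from conftest import ANISO, make_mask, random_mask
from oracles import (
    boundary_points_bruteforce,
    directed_h95_bruteforce,
    h95_allpairs,
    h95_bruteforce,
)


def points(*pts):
    return BoundaryPointSet(points=np.array(pts, dtype=float))


class TestDice:
    def test_identical_masks_give_100(self):
        m = random_mask((8, 8, 4), 0.4, seed=1)
        assert dice(m, m) == 100.0

    def test_disjoint_masks_give_0(self):
        a = make_mask(np.eye(4)[:, :, None].repeat(2, axis=2))
        b = make_mask(~a.grid & (np.arange(4)[:, None, None] < 2))
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        # |A| = 2, |G| = 2, |A ∩ G| = 1  ->  2*1/4*100 = 50
        a = np.zeros((4, 1, 1), bool); a[0] = a[1] = True
        g = np.zeros((4, 1, 1), bool); g[1] = g[2] = True
        assert dice(make_mask(a), make_mask(g)) == 50.0

    def test_both_empty_is_undefined(self):
        empty = make_mask(np.zeros((3, 3, 3), bool))
        with pytest.raises(UndefinedMetricError):
            dice(empty, empty)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_symmetric_and_bounded(self, seed):
        a = random_mask((7, 7, 5), 0.3, seed=seed)
        g = random_mask((7, 7, 5), 0.3, seed=seed + 1)
        d = dice(a, g)
        assert d == dice(g, a)
        assert 0.0 <= d <= 100.0

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_shrinking_false_positives_never_hurts(self, seed):
        # dropping voxels from A \ G moves A toward G: Dice must not decrease
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 4)) < 0.5
        g = rng.random((6, 6, 4)) < 0.5
        if not g.any():
            g[0, 0, 0] = True
        before = dice(make_mask(a), make_mask(g))
        fp = np.argwhere(a & ~g)
        if len(fp):
            drop = fp[rng.integers(len(fp))]
            a2 = a.copy(); a2[tuple(drop)] = False
            assert dice(make_mask(a2), make_mask(g)) >= before


class TestBoundary:
    def test_single_voxel_is_its_own_boundary(self):
        m = np.zeros((5, 5, 5), bool); m[2, 2, 2] = True
        b = extract_boundary(make_mask(m))
        assert b.count == 1
        np.testing.assert_allclose(b.points[0], [2 * 0.96, 2 * 0.96, 2 * 3.0])

    def test_solid_cube_boundary_is_shell(self):
        # 3x3x3 cube: only the center voxel is interior under 6-connectivity
        m = np.zeros((7, 7, 7), bool); m[2:5, 2:5, 2:5] = True
        assert extract_boundary(make_mask(m)).count == 26

    def test_image_border_counts_as_outside(self):
        # a mask filling the grid: the 26 edge voxels have all their in-grid
        # neighbors inside the mask, so they are boundary only because the
        # image border counts as outside; the center voxel stays interior
        m = np.ones((3, 3, 3), bool)
        assert extract_boundary(make_mask(m)).count == 26

    def test_empty_mask_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            extract_boundary(make_mask(np.zeros((3, 3, 3), bool)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_neighbor_scan(self, seed):
        m = random_mask((9, 8, 6), 0.45, seed=seed)
        got = {tuple(p) for p in extract_boundary(m).points}
        want = boundary_points_bruteforce(m.grid, ANISO)
        assert got == want


class TestH95:
    def test_identical_sets_give_zero(self):
        a = points((0, 0, 0), (1, 2, 3), (4, 5, 6))
        assert directed_h95(a, a) == 0.0
        assert h95(a, a) == 0.0

    def test_single_pair_one_slice_apart(self):
        # one voxel apart along z at dz = 3.0 mm
        a = points((0, 0, 0))
        g = points((0, 0, 3.0))
        assert directed_h95(a, g) == pytest.approx(3.0)
        assert h95(a, g) == pytest.approx(3.0)

    def test_kth_order_statistic_uses_ceil(self):
        # 10 collinear points vs a single target: minima are 0..9 mm and
        # K = ceil(0.95*10) = 10 picks the largest
        a = points(*[(float(i), 0, 0) for i in range(10)])
        g = points((0, 0, 0))
        assert directed_h95(a, g) == pytest.approx(9.0)
        # 20 points: K = ceil(19) = 19 picks the second largest
        a20 = points(*[(float(i), 0, 0) for i in range(20)])
        assert directed_h95(a20, g) == pytest.approx(18.0)

    def test_empty_set_is_an_error(self):
        with pytest.raises(UndefinedMetricError):
            directed_h95(BoundaryPointSet(np.empty((0, 3))), points((0, 0, 0)))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_sets_match_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = BoundaryPointSet(rng.uniform(0, 30, size=(100, 3)))
        g = BoundaryPointSet(rng.uniform(0, 30, size=(100, 3)))
        assert directed_h95(a, g) == pytest.approx(
            directed_h95_bruteforce(a.points, g.points), abs=1e-12
        )
        assert h95(a, g) == pytest.approx(h95_bruteforce(a.points, g.points), abs=1e-12)
        assert h95(a, g) == h95(g, a)


class TestAVD:
    def test_equal_volumes_give_zero(self):
        m = random_mask((6, 6, 4), 0.5, seed=2)
        assert avd(m, m) == 0.0

    @pytest.mark.parametrize("na,ng,want", [(110, 100, 10.0), (90, 100, 10.0)])
    def test_ten_percent_difference(self, na, ng, want):
        a = np.zeros((200, 1, 1), bool); a[:na] = True
        g = np.zeros((200, 1, 1), bool); g[:ng] = True
        assert avd(make_mask(a), make_mask(g)) == pytest.approx(want)

    def test_not_symmetric(self):
        a = np.zeros((4, 1, 1), bool); a[:1] = True
        g = np.zeros((4, 1, 1), bool); g[:2] = True
        assert avd(make_mask(a), make_mask(g)) != avd(make_mask(g), make_mask(a))

    def test_empty_reference_is_an_error(self):
        a = random_mask((3, 3, 3), 0.5, seed=0)
        with pytest.raises(UndefinedMetricError):
            avd(a, make_mask(np.zeros((3, 3, 3), bool)))


class TestSpacingBehavior:
    @pytest.mark.parametrize("lam", [0.5, 2.0, 3.7])
    def test_h95_scales_linearly_dice_avd_invariant(self, lam):
        base = ANISO
        scaled = tuple(lam * s for s in base)
        rng = np.random.default_rng(11)
        ga = rng.random((10, 9, 6)) < 0.4
        gg = rng.random((10, 9, 6)) < 0.4
        ga[0, 0, 0] = gg[1, 1, 1] = True
        a1, g1 = make_mask(ga, base), make_mask(gg, base)
        a2, g2 = make_mask(ga, scaled), make_mask(gg, scaled)
        h1 = h95(extract_boundary(a1), extract_boundary(g1))
        h2 = h95(extract_boundary(a2), extract_boundary(g2))
        assert h2 == pytest.approx(lam * h1)
        assert dice(a2, g2) == dice(a1, g1)
        assert avd(a2, g2) == avd(a1, g1)


class TestDegenerateCandidates:
    def test_empty_candidate_flags_h95_and_keeps_dice_avd(self):
        g = random_mask((5, 5, 3), 0.5, seed=4)
        a = make_mask(np.zeros((5, 5, 3), bool))
        t = mask_metrics(a, g)
        assert t.dice == 0.0
        assert t.avd == 100.0
        assert not t.h95_defined and np.isnan(t.h95)


class TestWMLSensitivity:
    def _vols(self, ref_grid, cand_grid):
        ref = LabelVolume(np.asarray(ref_grid, np.int16), ANISO, Scheme.RAW)
        cand = LabelVolume(np.asarray(cand_grid, np.int16), ANISO, Scheme.TISSUE)
        return cand, ref

    def test_all_lesions_as_wm_gives_100(self):
        ref = np.zeros((4, 1, 1), int); ref[:2] = 4
        cand = np.full((4, 1, 1), 2)
        c, r = self._vols(ref, cand)
        assert wml_sensitivity([c], [r]) == 100.0

    def test_all_lesions_as_gm_gives_0(self):
        ref = np.zeros((4, 1, 1), int); ref[:2] = 4
        cand = np.full((4, 1, 1), 1)
        c, r = self._vols(ref, cand)
        assert wml_sensitivity([c], [r]) == 0.0

    def test_pooled_over_cases(self):
        # 3 of 4 lesion voxels labeled WM across two cases -> 75
        ref1 = np.zeros((4, 1, 1), int); ref1[:2] = 4
        cand1 = np.full((4, 1, 1), 2)              # 2/2 hit
        ref2 = np.zeros((4, 1, 1), int); ref2[:2] = 4
        cand2 = np.array([2, 1, 0, 0]).reshape(4, 1, 1)  # 1/2 hit
        c1, r1 = self._vols(ref1, cand1)
        c2, r2 = self._vols(ref2, cand2)
        assert wml_sensitivity([c1, c2], [r1, r2]) == 75.0

    def test_no_lesions_anywhere_is_an_error(self):
        c, r = self._vols(np.zeros((2, 2, 2), int), np.zeros((2, 2, 2), int))
        with pytest.raises(UndefinedMetricError):
            wml_sensitivity([c], [r])


@pytest.mark.parametrize("seed", range(100))
def test_metric_oracle_battery(seed):
    """100 random mask pairs up to 20^3: Dice/H95/AVD against brute force."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 21, size=3))
    a = random_mask(shape, rng.uniform(0.05, 0.35), seed=seed * 2 + 1)
    g = random_mask(shape, rng.uniform(0.05, 0.35), seed=seed * 2 + 2)
    if not a.grid.any():
        a.grid[0, 0, 0] = True
    if not g.grid.any():
        g.grid[0, 0, 0] = True
    inter = int((a.grid & g.grid).sum())
    assert dice(a, g) == pytest.approx(200.0 * inter / (a.count + g.count))
    assert avd(a, g) == pytest.approx(abs(a.count - g.count) / g.count * 100.0)
    ba, bg = extract_boundary(a), extract_boundary(g)
    assert h95(ba, bg) == pytest.approx(h95_allpairs(ba.points, bg.points), abs=1e-12)
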