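import numpy as np
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from tractdistill.evaluation import (
    bundle_adjacency,
    bundle_geometry,
    compare_methods,
    mann_whitney_u,
    streamline_density,
    voxel_dice,
)
from tractdistill.geometry import ScalarVolume, Tractogram, VoxelGrid

from oracles import mwu_oracle


@pytest.fixture
def grid2mm():
    return VoxelGrid.isotropic((10, 10, 10), 2.0)


def _mask(grid, coords):
    m = np.zeros(grid.shape)
    for c in coords:
        m[c] = 1.0
    return ScalarVolume(grid, m)


class TestStreamlineDensity:
    def test_empty_tractogram_all_zero(self, grid2mm):
        counts, mask = streamline_density(Tractogram([], grid2mm), grid2mm)
        assert not counts.values.any()
        assert not mask.values.any()

    def test_axis_aligned_line_crosses_k_voxels(self, grid2mm):
        # from voxel center (2,4,4) to (6,4,4): 5 voxel centers crossed
        s = np.array([[4.0, 8.0, 8.0], [12.0, 8.0, 8.0]])
        counts, mask = streamline_density(Tractogram([s], grid2mm), grid2mm)
        assert int(mask.values.sum()) == 5
        assert counts.values.max() == 1

    def test_duplicate_streamline_doubles_counts_same_mask(self, grid2mm):
        s = np.array([[4.0, 8.0, 8.0], [12.0, 8.0, 8.0]])
        c1, m1 = streamline_density(Tractogram([s], grid2mm), grid2mm)
        c2, m2 = streamline_density(Tractogram([s, s.copy()], grid2mm), grid2mm)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(2 * c1.values, c2.values)

    def test_out_of_grid_points_ignored(self, grid2mm):
        s = np.array([[-30.0, 8.0, 8.0], [4.0, 8.0, 8.0]])
        counts, _ = streamline_density(Tractogram([s], grid2mm), grid2mm)
        assert counts.values.sum() > 0  # inside part voxelized, no raise


class TestVoxelDice:
    def test_identical_nonempty_is_one(self, grid2mm):
        m = _mask(grid2mm, [(1, 1, 1), (2, 2, 2)])
        assert voxel_dice(m, m) == 1.0

    def test_disjoint_is_zero(self, grid2mm):
        a = _mask(grid2mm, [(1, 1, 1)])
        b = _mask(grid2mm, [(5, 5, 5)])
        assert voxel_dice(a, b) == 0.0

    def test_half_overlap(self, grid2mm):
        a = _mask(grid2mm, [(1, 1, 1), (2, 2, 2)])
        b = _mask(grid2mm, [(2, 2, 2), (3, 3, 3)])
        assert voxel_dice(a, b) == 0.5

    def test_symmetry_and_bounds(self, grid2mm, rng):
        for _ in range(20):
            a = ScalarVolume(grid2mm, (rng.uniform(size=grid2mm.shape) > 0.7).astype(float))
            b = ScalarVolume(grid2mm, (rng.uniform(size=grid2mm.shape) > 0.7).astype(float))
            d = voxel_dice(a, b)
            assert d == voxel_dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_both_empty_is_zero_by_convention(self, grid2mm):
        e = _mask(grid2mm, [])
        assert voxel_dice(e, e) == 0.0

    def test_grid_mismatch(self, grid2mm):
        other = VoxelGrid.isotropic((8, 8, 8), 2.0)
        with pytest.raises(ValueError, match="mismatch"):
            voxel_dice(_mask(grid2mm, []), _mask(other, []))


class TestBundleAdjacency:
    def _line(self, offset=0.0):
        x = np.linspace(2.0, 16.0, 15)
        return np.stack([x, np.full_like(x, 8.0 + offset), np.full_like(x, 8.0)], axis=1)

    def test_self_is_zero(self, grid2mm):
        tg = Tractogram([self._line()], grid2mm)
        assert bundle_adjacency(tg, tg) == 0.0

    def test_superset_is_zero(self, grid2mm):
        ref = Tractogram([self._line()], grid2mm)
        other = Tractogram([self._line(), self._line(4.0)], grid2mm)
        assert bundle_adjacency(ref, other) == 0.0

    def test_perpendicular_translation(self, grid2mm):
        ref = Tractogram([self._line()], grid2mm)
        other = Tractogram([self._line(2.0)], grid2mm)
        assert bundle_adjacency(ref, other) == pytest.approx(2.0, abs=1e-12)

    def test_translation_bounds_change(self, grid2mm, rng):
        ref = Tractogram([self._line(), self._line(3.0)], grid2mm)
        t = rng.normal(size=3)
        moved = Tractogram([s + t for s in ref.streamlines], grid2mm)
        assert bundle_adjacency(ref, moved) <= np.linalg.norm(t) + 1e-12

    def test_empty_other_rejected(self, grid2mm):
        ref = Tractogram([self._line()], grid2mm)
        with pytest.raises(ValueError, match="empty"):
            bundle_adjacency(ref, Tractogram([], grid2mm))


class TestBundleGeometry:
    def test_straight_line_length(self, grid2mm):
        pts = np.stack([np.arange(10.0), np.full(10, 8.0), np.full(10, 8.0)], axis=1)
        g = bundle_geometry(Tractogram([pts], grid2mm), grid2mm)
        assert g.avg_length_mm == pytest.approx(9.0)

    def test_single_voxel_cube_arithmetic(self, grid2mm):
        # stays strictly inside voxel (4,4,4): volume 8 mm^3, 6 faces x 4 mm^2
        pts = np.array([[7.6, 8.0, 8.0], [8.4, 8.0, 8.0]])
        g = bundle_geometry(Tractogram([pts], grid2mm), grid2mm)
        assert g.volume_mm3 == pytest.approx(8.0)
        assert g.surface_area_mm2 == pytest.approx(24.0)

    def test_three_voxel_run(self, grid2mm):
        pts = np.array([[4.0, 8.0, 8.0], [12.0, 8.0, 8.0]])  # centers 2,3,4,5,6 -> 5 voxels
        pts = np.array([[6.0, 8.0, 8.0], [10.0, 8.0, 8.0]])  # centers 3,4,5 -> 3 voxels
        g = bundle_geometry(Tractogram([pts], grid2mm), grid2mm)
        assert g.volume_mm3 == pytest.approx(24.0)
        assert g.surface_area_mm2 == pytest.approx(56.0)

    def test_cylinder_diameter_estimate(self):
        # dense cylinder of parallel streamlines, radius 4 mm, length 40 mm
        grid = VoxelGrid.isotropic((32, 16, 16), 2.0)
        rng = np.random.default_rng(0)
        lines = []
        for _ in range(300):
            r = 4.0 * np.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * np.pi)
            y, z = 15.0 + r * np.cos(a), 15.0 + r * np.sin(a)
            x = np.linspace(10.0, 50.0, 41)
            lines.append(np.stack([x, np.full_like(x, y), np.full_like(x, z)], axis=1))
        g = bundle_geometry(Tractogram(lines, grid), grid)
        assert abs(g.diameter_mm - 8.0) / 8.0 < 0.30

    def test_empty_rejected(self, grid2mm):
        with pytest.raises(ValueError, match="empty"):
            bundle_geometry(Tractogram([], grid2mm), grid2mm)


class TestMannWhitney:
    def test_fully_separated_pairs(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_all_ties(self):
        a = [2.0, 2.0, 2.0]
        u, p = mann_whitney_u(a, list(a))
        assert u == len(a) ** 2 / 2
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_samples(self, rng):
        for _ in range(15):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 5))
            a = rng.integers(0, 4, size=n1).astype(float)  # integer values force ties
            b = rng.integers(0, 4, size=n2).astype(float)
            u, p = mann_whitney_u(a, b)
            u_want, p_want = mwu_oracle(a, b)
            assert u == pytest.approx(u_want)
            assert p == pytest.approx(p_want, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        u, p = mann_whitney_u(a, b)
        res = scipy_mwu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(res.statistic))
        assert p == pytest.approx(float(res.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCompareMethods:
    def _labeled(self, grid, offset=0.0, drop_bundle=None):
        lines, ids = [], []
        for bundle, y in ((1, 6.0), (2, 12.0)):
            if bundle == drop_bundle:
                continue
            for k in range(3):
                x = np.linspace(2.0, 16.0, 15)
                lines.append(
                    np.stack(
                        [x, np.full_like(x, y + offset), np.full_like(x, 8.0 + k * 0.5)],
                        axis=1,
                    )
                )
                ids.append(bundle)
        return Tractogram(lines, grid, np.asarray(ids))

    def test_identical_candidate(self, grid2mm):
        ref = self._labeled(grid2mm)
        report = compare_methods(ref, {"copy": ref})
        cand = report[report.method == "copy"]
        assert np.allclose(cand.dice, 1.0)
        assert np.allclose(cand.bundle_adjacency_mm, 0.0)
        ref_rows = report[report.method == "reference"]
        for m in ("avg_length_mm", "volume_mm3", "diameter_mm", "surface_area_mm2"):
            assert np.allclose(cand[m].values, ref_rows[m].values)

    def test_deleted_bundle_scores_zero_dice(self, grid2mm):
        ref = self._labeled(grid2mm)
        cand = self._labeled(grid2mm, drop_bundle=2)
        report = compare_methods(ref, {"partial": cand})
        row = report[(report.method == "partial") & (report.bundle == "2")].iloc[0]
        assert row.dice == 0.0
        assert np.isnan(row.bundle_adjacency_mm)
        whole = report[(report.method == "partial") & (report.bundle == "all")].iloc[0]
        assert whole.dice < 1.0

    def test_row_count(self, grid2mm):
        ref = self._labeled(grid2mm)
        cand = self._labeled(grid2mm, offset=0.5)
        report = compare_methods(ref, {"a": cand, "b": cand})
        assert len(report) == (2 + 1) * (2 + 1)

    def test_missing_labels_rejected(self, grid2mm):
        ref = self._labeled(grid2mm)
        unlabeled = Tractogram(ref.streamlines, grid2mm)
        with pytest.raises(ValueError, match="label"):
            compare_methods(unlabeled, {"x": ref})
        with pytest.raises(ValueError, match="label"):
            compare_methods(ref, {"x": unlabeled})
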