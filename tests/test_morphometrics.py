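"""Voxel counting, face area, discrete compactness and SOAM tortuosity."""

import numpy as np
import pytest

from _oracles import brute_force_angle_sum, brute_force_face_count, sample_arc_path
from neuromorph import (
    BinaryMask,
    CurveSpec,
    MetricsConfig,
    SkeletonPath,
    discrete_compactness,
    exposed_face_area,
    make_tube_phantom,
    normalized_volume,
    plane_angle,
    soam_tortuosity,
    structure_metrics,
    voxel_count,
)


def _mask(data, spacing=1.0):
    return BinaryMask(np.asarray(data, dtype=bool), np.full(3, spacing))


class TestVoxelCount:
    def test_empty_and_cube(self):
        assert voxel_count(_mask(np.zeros((4, 4, 4)))) == 0
        assert voxel_count(_mask(np.ones((10, 10, 10)))) == 1000

    def test_matches_loop_oracle(self, rng):
        data = rng.random((6, 6, 6)) > 0.5
        count = sum(
            1
            for i in range(6)
            for j in range(6)
            for k in range(6)
            if data[i, j, k]
        )
        assert voxel_count(_mask(data)) == count


class TestNormalizedVolume:
    def test_basic_ratios(self):
        assert normalized_volume(100, 1000) == pytest.approx(0.1)
        assert normalized_volume(500, 500) == pytest.approx(1.0)

    def test_partition_identity(self):
        n_gm, n_wm, n_csf = 500, 300, 200
        icv = n_gm + n_wm + n_csf
        total = sum(normalized_volume(n, icv) for n in (n_gm, n_wm, n_csf))
        assert total == pytest.approx(1.0)

    def test_exceeding_icv_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            assert normalized_volume(11, 10) == pytest.approx(1.1)


class TestExposedFaceArea:
    @pytest.mark.parametrize(
        "shape_fn, expected",
        [
            (lambda: np.ones((1, 1, 1)), 6),     # single voxel
            (lambda: np.ones((2, 1, 1)), 10),    # domino
            (lambda: np.ones((3, 3, 3)), 54),    # cube: 6 * 3^2
            (lambda: np.ones((1, 1, 8)), 34),    # rod
        ],
    )
    def test_known_shapes(self, shape_fn, expected):
        assert exposed_face_area(_mask(shape_fn())) == expected

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            data = rng.random((5, 5, 5)) > 0.6
            assert exposed_face_area(_mask(data)) == brute_force_face_count(data)

    def test_anisotropic_spacing_rejected(self):
        mask = BinaryMask(np.ones((2, 2, 2), bool), np.array([1.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="resample"):
            exposed_face_area(mask)


class TestDiscreteCompactness:
    def test_solid_cube_is_fully_compact(self):
        # n = 1000, A = 600 -> (1000 - 100) / (1000 - 100) = 1
        assert discrete_compactness(1000, 600) == pytest.approx(1.0)

    def test_solid_cubes_of_any_side(self):
        for side in (2, 3, 4, 6, 10):
            m = _mask(np.ones((side, side, side)))
            dc = discrete_compactness(voxel_count(m), exposed_face_area(m))
            assert dc == pytest.approx(1.0, abs=1e-12)

    def test_face_disconnected_scatter_is_null(self):
        # 8 pairwise non-face-adjacent voxels: corners of a 3^3 lattice
        data = np.zeros((3, 3, 3), dtype=bool)
        for i in (0, 2):
            for j in (0, 2):
                for k in (0, 2):
                    data[i, j, k] = True
        m = _mask(data)
        assert discrete_compactness(voxel_count(m), exposed_face_area(m)) == 0.0

    def test_rod_value_against_face_count_oracle(self):
        data = np.ones((1, 1, 8), dtype=bool)
        n = 8
        a = brute_force_face_count(data)
        assert a == 34
        assert discrete_compactness(n, a) == pytest.approx(7.0 / 12.0)

    def test_single_voxel_convention(self):
        assert discrete_compactness(1, 6) == 0.0

    def test_zero_voxels_rejected(self):
        with pytest.raises(ValueError):
            discrete_compactness(0, 0)

    def test_invariant_to_translation_and_lattice_rotation(self, rng):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[2:7, 3:8, 1:6] = rng.random((5, 5, 5)) > 0.3

        def dc(d):
            m = _mask(d)
            return discrete_compactness(voxel_count(m), exposed_face_area(m))

        base = dc(data)
        assert dc(np.roll(data, (2, 1, 3), axis=(0, 1, 2))) == pytest.approx(base)
        assert dc(np.rot90(data, k=1, axes=(0, 1))) == pytest.approx(base)
        assert dc(np.rot90(data, k=3, axes=(1, 2))) == pytest.approx(base)


class TestPlaneAngle:
    @pytest.mark.parametrize(
        "triad, expected",
        [
            (((0, 0, 0), (1, 0, 0), (2, 0, 0)), 0.0),
            (((0, 0, 0), (1, 0, 0), (1, 1, 0)), np.pi / 2),
            (((0, 0, 0), (1, 0, 0), (2, 1, 0)), np.pi / 4),
        ],
    )
    def test_known_angles(self, triad, expected):
        assert plane_angle(*triad) == pytest.approx(expected)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            plane_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestSoamTortuosity:
    def test_collinear_path_has_zero_tortuosity(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        tr, angle_sum, length = soam_tortuosity([SkeletonPath(pts)])
        assert tr == 0.0
        assert angle_sum == 0.0
        assert length == pytest.approx(9.0)

    def test_l_path_worked_example(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0], [1, 3, 0]], dtype=float
        )
        tr, angle_sum, length = soam_tortuosity([SkeletonPath(pts)])
        # eligible angles (k = 1..N-3): pi/2 then 0; total length 4
        assert angle_sum == pytest.approx(np.pi / 2)
        assert length == pytest.approx(4.0)
        assert tr == pytest.approx(np.pi / 2 / 4)

    @pytest.mark.parametrize("radius", [10.0, 20.0, 40.0])
    def test_dense_arc_recovers_curvature(self, radius):
        pts = sample_arc_path(radius, d_theta_deg=0.5)
        tr, _, _ = soam_tortuosity([SkeletonPath(pts)])
        assert tr == pytest.approx(1.0 / radius, rel=0.03)

    def test_scaling_divides_tortuosity_exactly(self, rng):
        pts = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        tr, angle_sum, length = soam_tortuosity([SkeletonPath(pts)])
        s = 2.5
        tr_s, angle_s, length_s = soam_tortuosity([SkeletonPath(pts * s)])
        assert angle_s == pytest.approx(angle_sum, abs=1e-9)
        assert length_s == pytest.approx(length * s)
        assert tr_s == pytest.approx(tr / s)

    def test_rotation_invariance(self, rng):
        pts = np.cumsum(rng.normal(size=(25, 3)), axis=0)
        theta = 1.1
        R = np.array(
            [[1, 0, 0],
             [0, np.cos(theta), -np.sin(theta)],
             [0, np.sin(theta), np.cos(theta)]]
        )
        tr, _, _ = soam_tortuosity([SkeletonPath(pts)])
        tr_rot, _, _ = soam_tortuosity([SkeletonPath(pts @ R.T)])
        assert tr_rot == pytest.approx(tr)

    def test_reversal_differs_only_by_dropped_window_angle(self, rng):
        # the N-3 window drops the last interior angle; reversal drops the
        # first instead, so forward/reverse TR differ by at most that angle
        pts = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        tr_f, _, length = soam_tortuosity([SkeletonPath(pts)])
        tr_r, _, _ = soam_tortuosity([SkeletonPath(pts[::-1].copy())])
        angles = [
            brute_force_angle_sum(pts[k - 1 : k + 2], 1) for k in range(1, 19)
        ]
        assert abs(tr_f - tr_r) <= max(angles) / length + 1e-12

    def test_angle_sum_matches_triad_loop_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            pts = np.cumsum(rng.normal(size=(n, 3)), axis=0)
            _, angle_sum, _ = soam_tortuosity([SkeletonPath(pts)])
            assert angle_sum == pytest.approx(
                brute_force_angle_sum(pts, n - 3), abs=1e-12
            )

    def test_all_interior_angles_variant(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0], [2, 2, 0]], dtype=float
        )
        _, window_sum, _ = soam_tortuosity([SkeletonPath(pts)])
        _, full_sum, _ = soam_tortuosity(
            [SkeletonPath(pts)], all_interior_angles=True
        )
        assert window_sum == pytest.approx(brute_force_angle_sum(pts, 2), abs=1e-12)
        assert full_sum == pytest.approx(brute_force_angle_sum(pts, 3), abs=1e-12)

    def test_arc_monotone_in_radius(self):
        trs = []
        for radius in (40.0, 20.0, 10.0):
            pts = sample_arc_path(radius, d_theta_deg=1.0)
            tr, _, _ = soam_tortuosity([SkeletonPath(pts)])
            trs.append(tr)
        assert trs[0] < trs[1] < trs[2]

    def test_short_path_lengths_enter_denominator(self):
        long = SkeletonPath(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0], [1, 3, 0]], float)
        )
        short = SkeletonPath(np.array([[5, 5, 5], [6, 5, 5]], float),
                             angle_eligible=False)
        tr_with, angle_with, len_with = soam_tortuosity([long, short])
        tr_alone, angle_alone, len_alone = soam_tortuosity([long])
        assert angle_with == pytest.approx(angle_alone)
        assert len_with == pytest.approx(len_alone + 1.0)
        assert tr_with < tr_alone

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            soam_tortuosity([SkeletonPath(np.zeros((1, 3)))])


class TestStructureMetrics:
    def test_solid_cube_composition(self, solid_cube_mask):
        m = structure_metrics(solid_cube_mask, icv=2000, structure="cube")
        assert m.n == 1000
        assert m.V == pytest.approx(1000.0)
        assert m.NV == pytest.approx(0.5)
        assert m.DC == pytest.approx(1.0)

    def test_straight_tube_is_straight(self):
        mask, _, _ = make_tube_phantom(
            CurveSpec(kind="line", length=40), tube_radius=3, spacing=1.0
        )
        m = structure_metrics(mask, icv=mask.count, structure="tube")
        assert m.TR < 0.01

    def test_arc_tube_recovers_generating_curvature(self):
        mask, expected_tr, _ = make_tube_phantom(
            CurveSpec(kind="arc", radius=20.0, length=31.4), tube_radius=3,
            spacing=1.0,
        )
        cfg = MetricsConfig(smoothing_window=11)
        m = structure_metrics(mask, icv=mask.count, config=cfg, structure="arc")
        assert m.TR == pytest.approx(expected_tr, rel=0.15)

    def test_tr_times_length_equals_angle_sum(self):
        mask, _, _ = make_tube_phantom(
            CurveSpec(kind="arc", radius=15.0, length=20.0), tube_radius=3,
            spacing=1.0,
        )
        m = structure_metrics(mask, icv=mask.count)
        assert m.TR * m.skel_length == pytest.approx(m.angle_sum, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            structure_metrics(
                BinaryMask(np.zeros((3, 3, 3), bool), np.ones(3)), icv=100
            )
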