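import itertools

import numpy as np
import pytest

import avve
from avve.errors import GridAlignmentError
from avve.voxel_features import CardinalityConfig, NeighborRule, OFFSETS_26


def _unit_volume(data):
    return avve.VolumeImage(np.asarray(data, dtype=float), np.eye(4), (1, 1, 1))


def brute_force_neighboring(data, ratio=0.2):
    """Triple-loop oracle for the 26-direction relative-contrast count."""
    data = np.asarray(data, dtype=float)
    out = np.zeros(data.shape, dtype=int)
    shape = data.shape
    for i, j, k in np.ndindex(shape):
        c = 0
        for a, b, d in itertools.product((-1, 0, 1), repeat=3):
            if (a, b, d) == (0, 0, 0):
                continue
            ni, nj, nk = i + a, j + b, k + d
            mi, mj, mk = i + 2 * a, j + 2 * b, k + 2 * d
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if not (0 <= mi < shape[0] and 0 <= mj < shape[1] and 0 <= mk < shape[2]):
                continue
            near = abs(data[i, j, k] - data[ni, nj, nk])
            far = abs(data[ni, nj, nk] - data[mi, mj, mk])
            if near > ratio * far:
                c += 1
        out[i, j, k] = c
    return out


class TestNormalizedDistance:
    def test_pythagorean_triple_from_corner_origin(self):
        vol = _unit_volume(np.zeros((8, 8, 8)))  # identity affine: SCV at (0,0,0)
        nd = avve.normalized_distance(vol)
        assert nd[0, 0, 0] == 0.0
        assert nd[3, 4, 0] == pytest.approx(5.0)

    def test_matches_brute_force_distances(self, rng):
        affine = np.diag([1.0, 1.0, 1.0, 1.0])
        affine[:3, 3] = (-3.2, -4.7, -1.1)  # fractional SCV inside the grid
        vol = avve.VolumeImage(rng.normal(size=(9, 9, 9)), affine, (1, 1, 1))
        nd = avve.normalized_distance(vol)
        scv = np.linalg.inv(affine)[:3, 3]
        for idx in [(0, 0, 0), (4, 4, 4), (8, 2, 5)]:
            expected = np.linalg.norm(np.asarray(idx) - scv)
            assert nd[idx] == pytest.approx(expected, rel=1e-5)
        assert nd.min() >= 0.0

    def test_scv_may_lie_outside_the_grid(self):
        affine = np.eye(4)
        affine[:3, 3] = (50.0, 50.0, 50.0)  # restricted FOV far from isocenter
        vol = avve.VolumeImage(np.zeros((4, 4, 4)), affine, (1, 1, 1))
        nd = avve.normalized_distance(vol)
        assert np.all(nd > 0)

    def test_invariant_under_intensity_relabeling(self, rng):
        affine = np.eye(4)
        affine[:3, 3] = (-4.0, -4.0, -4.0)
        a = avve.VolumeImage(rng.normal(size=(8, 8, 8)), affine, (1, 1, 1))
        b = avve.VolumeImage(rng.uniform(100, 200, (8, 8, 8)), affine, (1, 1, 1))
        np.testing.assert_array_equal(
            avve.normalized_distance(a), avve.normalized_distance(b)
        )

    def test_scales_with_voxel_volume(self):
        vol = avve.VolumeImage(
            np.zeros((6, 6, 6)), np.diag([0.5, 0.5, 2.0, 1.0]), (0.5, 0.5, 2.0)
        )
        nd = avve.normalized_distance(vol)
        # index distance to (0,0,0) times voxel volume 0.5*0.5*2 = 0.5
        assert nd[3, 4, 0] == pytest.approx(5.0 * 0.5)


class TestCardinality:
    def test_origin_voxel_in_first_block(self):
        vol = _unit_volume(np.zeros((8, 8, 8)))
        card = avve.cardinality(vol, CardinalityConfig(4, 4, 4))
        assert card[0, 0, 0] == 1

    def test_whole_axis_dividers_collapse_to_one_block(self):
        vol = _unit_volume(np.zeros((8, 8, 8)))
        card = avve.cardinality(vol, CardinalityConfig(8, 8, 8))
        assert np.all(card == 1)

    def test_eight_cube_blocks_enumerated_consecutively(self):
        vol = _unit_volume(np.zeros((8, 8, 8)))
        card = avve.cardinality(vol, CardinalityConfig(4, 4, 4))
        assert set(np.unique(card)) == set(range(1, 9))
        for value in range(1, 9):
            assert (card == value).sum() == 4**3
        # consecutive blocks along x differ by 1
        assert card[4, 0, 0] - card[0, 0, 0] == 1

    def test_blocks_partition_the_grid(self, rng):
        vol = _unit_volume(rng.normal(size=(10, 12, 9)))
        card = avve.cardinality(vol, CardinalityConfig(4, 5, 3))
        values, counts = np.unique(card, return_counts=True)
        assert counts.sum() == vol.data.size
        assert values.min() == 1
        # every block is an axis-aligned box: its index range is contiguous
        for v in values:
            where = np.argwhere(card == v)
            lo, hi = where.min(axis=0), where.max(axis=0)
            assert len(where) == np.prod(hi - lo + 1)

    def test_oversized_divider_clamps_to_axis(self):
        vol = _unit_volume(np.zeros((6, 6, 6)))
        card = avve.cardinality(vol, CardinalityConfig(100, 100, 100))
        assert np.all(card == 1)


class TestNeighboring:
    def test_constant_volume_scores_zero(self):
        vol = _unit_volume(np.full((6, 6, 6), 42.0))
        assert np.all(avve.neighboring(vol) == 0)

    def test_isolated_bright_voxel_reaches_upper_bound(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 100.0
        counts = avve.neighboring(_unit_volume(data))
        assert counts[2, 2, 2] == 26

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = r.uniform(0, 100, size=(6, 6, 6))
            vol = _unit_volume(data)
            np.testing.assert_array_equal(
                avve.neighboring(vol), brute_force_neighboring(data)
            )

    def test_range_bounded_by_26(self, rng):
        vol = _unit_volume(rng.normal(size=(7, 7, 7)))
        counts = avve.neighboring(vol)
        assert counts.min() >= 0 and counts.max() <= 26

    def test_offset_set_has_26_directions(self):
        assert len(OFFSETS_26) == 26
        assert (0, 0, 0) not in OFFSETS_26

    def test_ratio_must_be_positive(self):
        with pytest.raises(ValueError):
            NeighborRule(ratio=0.0)


class TestCandidatePool:
    def test_constant_volume_has_zero_derivative_features(self):
        pool = avve.candidate_pool(_unit_volume(np.full((8, 8, 8), 9.0)))
        # truncated Gaussian-derivative kernels leave a ~1e-3 residual
        for name in ("laplacian", "log_sigma1", "log_sigma2", "log_sigma3"):
            np.testing.assert_allclose(pool[name], 0.0, atol=1e-2)

    def test_intensity_channel_is_identity(self, rng):
        data = rng.normal(size=(6, 6, 6))
        pool = avve.candidate_pool(_unit_volume(data))
        np.testing.assert_array_equal(pool["intensity"], data)

    def test_laplacian_stencil_at_bright_voxel(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 10.0
        lap = avve.candidate_pool(_unit_volume(data))["laplacian"]
        assert lap[2, 2, 2] < 0
        for off in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            assert lap[2 + off[0], 2 + off[1], 2 + off[2]] > 0


GEOM_FEATURES = ("normalized_distance", "cardinality", "neighboring", "intensity")


class TestFeatureTable:
    def _pair(self, rng, shape=(10, 10, 10)):
        vol = _unit_volume(rng.uniform(0, 100, size=shape))
        mask = avve.BinaryMask(
            rng.random(shape) < 0.1, vol.affine, vol.spacing
        )
        return vol, mask

    def test_row_and_column_arithmetic(self, rng):
        v1, m1 = self._pair(rng)
        v2, m2 = self._pair(rng)
        table = avve.build_feature_table([v1, v2], [m1, m2], features=GEOM_FEATURES)
        assert len(table.frame) == 2000
        assert table.frame.shape[1] == 6  # 4 features + label + subject_id
        assert table.has_labels

    def test_misaligned_mask_rejected(self, rng):
        vol, _ = self._pair(rng)
        bad = avve.BinaryMask(np.zeros((9, 10, 10), dtype=bool), vol.affine,
                              vol.spacing)
        with pytest.raises(GridAlignmentError):
            avve.build_feature_table([vol], [bad], features=GEOM_FEATURES)

    def test_label_mass_is_conserved(self, rng):
        v1, m1 = self._pair(rng)
        v2, m2 = self._pair(rng)
        table = avve.build_feature_table([v1, v2], [m1, m2], features=GEOM_FEATURES)
        assert table.labels().sum() == m1.data.sum() + m2.data.sum()

    def test_inference_table_omits_labels(self, rng):
        vol, _ = self._pair(rng)
        table = avve.build_feature_table([vol], None, features=GEOM_FEATURES)
        assert not table.has_labels

    def test_absent_mask_yields_zero_labels(self, rng):
        v1, m1 = self._pair(rng)
        v2, _ = self._pair(rng)
        table = avve.build_feature_table([v1, v2], [m1, None], features=GEOM_FEATURES)
        by_subject = table.frame.groupby("subject_id")["label"].sum()
        assert by_subject["subject-001"] == 0

    def test_rows_in_c_order_allow_mask_reconstruction(self, rng):
        vol, mask = self._pair(rng)
        table = avve.build_feature_table([vol], [mask], features=GEOM_FEATURES)
        rebuilt = table.labels().reshape(table.grids["subject-000"].shape)
        np.testing.assert_array_equal(rebuilt.astype(bool), mask.data)

    def test_csv_round_trip(self, rng, tmp_path):
        import pandas as pd

        vol, mask = self._pair(rng, shape=(6, 6, 6))
        table = avve.build_feature_table([vol], [mask], features=GEOM_FEATURES)
        table.to_csv(tmp_path / "table.csv")
        back = pd.read_csv(tmp_path / "table.csv")
        assert list(back.columns) == list(GEOM_FEATURES) + ["label", "subject_id"]
        assert len(back) == len(table.frame)
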