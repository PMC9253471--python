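import numpy as np
import pytest

from disco import (
    TemplateGrid,
    Tractogram,
    read_tractogram,
    write_tractogram,
    read_volume,
    write_volume,
    resample_streamline,
    streamline_voxels,
    visitation_map,
    select_through_mask,
)
from disco.tractogram import TractogramParseError
from tests.conftest import straight_streamline


class TestResample:
    def test_two_points_one_mm_step_half(self):
        s = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        out = resample_streamline(s, 0.5)
        assert len(out) == 3
        assert np.allclose(out[:, 0], [0, 0.5, 1.0])

    def test_ten_mm_segment_step_half_preserves_arc_length(self):
        s = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        out = resample_streamline(s, 0.5)
        assert len(out) == 21
        arc = np.linalg.norm(np.diff(out, axis=0), axis=1).sum()
        assert arc == pytest.approx(10.0, abs=1e-12)

    def test_spacing_bound_and_endpoints(self):
        rng = np.random.default_rng(7)
        s = np.cumsum(rng.normal(0, 1, size=(20, 3)), axis=0)
        out = resample_streamline(s, 0.3)
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert gaps.max() <= 0.3 + 1e-12
        assert np.allclose(out[0], s[0]) and np.allclose(out[-1], s[-1])

    def test_already_dense_input_keeps_bound(self):
        s = np.column_stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)])
        out = resample_streamline(s, 0.5)
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert gaps.max() <= 0.5

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            resample_streamline(np.array([[0.0, 0, 0], [1, 0, 0]]), 0.0)


class TestStreamlineVoxels:
    def test_straight_line_through_five_unit_voxels(self, grid16):
        s = np.array([[2.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        voxels = streamline_voxels(s, grid16)
        assert voxels == {(x, 5, 5) for x in range(2, 7)}

    def test_streamline_outside_grid_is_empty(self, grid16):
        s = np.array([[100.0, 100, 100], [120.0, 100, 100]])
        assert streamline_voxels(s, grid16) == set()

    def test_step_larger_than_half_voxel_rejected(self, grid16):
        s = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        with pytest.raises(ValueError):
            streamline_voxels(s, grid16, step=0.9)

    def test_diagonal_matches_dense_sampling_oracle(self, grid16):
        s = np.array([[1.0, 1.0, 1.0], [9.0, 9.0, 9.0]])
        got = streamline_voxels(s, grid16, step=0.25)
        dense = streamline_voxels(s, grid16, step=0.01)
        assert got == dense

    def test_random_streamlines_agree_with_dense_oracle(self, grid16):
        """Voxelisation agrees with a 0.01 mm dense-sampling oracle up to
        corner-grazed voxels: any voxel the oracle finds but the default
        step misses must be crossed by a chord shorter than the step
        (such a voxel can carry no sample by construction)."""
        rng = np.random.default_rng(0)
        step = 0.25
        for _ in range(100):
            pts = rng.uniform(1, 14, size=(4, 3))
            got = streamline_voxels(pts, grid16, step=step)
            dense_pts = resample_streamline(pts, 0.01)
            ijk = grid16.nearest_voxel(dense_pts)
            dense = {tuple(v) for v in ijk[grid16.inside(ijk)]}
            assert got <= dense
            for missed in dense - got:
                inside = np.all(ijk == missed, axis=1)
                # each contiguous crossing of the voxel must be shorter
                # than the step (a crossing may happen more than once)
                runs = np.diff(np.flatnonzero(np.diff(np.r_[0, inside, 0])))[::2]
                assert (0.01 * runs.max()) < step


class TestVisitationMap:
    def test_single_streamline_counts_binary(self, grid16):
        t = Tractogram(streamlines=[straight_streamline(5, 5)])
        counts = visitation_map(t, grid16)
        assert set(np.unique(counts)) <= {0, 1}

    def test_identical_streamlines_share_support(self, grid16):
        s = straight_streamline(5, 5)
        t = Tractogram(streamlines=[s.copy() for _ in range(20)])
        counts = visitation_map(t, grid16)
        assert set(np.unique(counts)) == {0, 20}
        single = visitation_map(Tractogram(streamlines=[s]), grid16)
        assert np.array_equal(counts > 0, single > 0)

    def test_two_bundles_sum_in_shared_voxel(self, grid16):
        a = [straight_streamline(5, 5) for _ in range(3)]
        # perpendicular bundle crossing (8, 5, 5)
        b = [
            np.column_stack([np.full(10, 8.0), np.linspace(2, 13, 10), np.full(10, 5.0)])
            for _ in range(4)
        ]
        counts = visitation_map(Tractogram(streamlines=a + b), grid16)
        assert counts[8, 5, 5] == 7

    def test_support_is_union_of_streamline_voxel_sets(self, grid16):
        rng = np.random.default_rng(3)
        streamlines = [rng.uniform(1, 14, size=(4, 3)) for _ in range(10)]
        t = Tractogram(streamlines=streamlines)
        counts = visitation_map(t, grid16)
        union = set()
        for s in streamlines:
            union |= streamline_voxels(s, grid16)
        got = {tuple(v) for v in np.argwhere(counts > 0)}
        assert got == union


class TestSelectThroughMask:
    def test_disjoint_mask_selects_nothing(self, grid16):
        t = Tractogram(streamlines=[straight_streamline(5, 5)])
        mask = np.zeros(grid16.shape, dtype=bool)
        mask[0, 0, 0] = True
        assert len(select_through_mask(t, mask, grid16)) == 0

    def test_full_mask_is_identity(self, grid16):
        t = Tractogram(streamlines=[straight_streamline(5, 5), straight_streamline(8, 8)])
        mask = np.ones(grid16.shape, dtype=bool)
        sel = select_through_mask(t, mask, grid16)
        assert len(sel) == len(t)
        for a, b in zip(sel, t):
            assert np.array_equal(a, b)

    def test_selection_matches_per_streamline_oracle(self, grid16):
        rng = np.random.default_rng(11)
        streamlines = [rng.uniform(1, 14, size=(3, 3)) for _ in range(30)]
        t = Tractogram(streamlines=streamlines)
        mask = np.zeros(grid16.shape, dtype=bool)
        mask[4:8, 4:8, 4:8] = True
        sel = select_through_mask(t, mask, grid16)
        expected = [
            s for s in streamlines
            if any(mask[v] for v in streamline_voxels(s, grid16))
        ]
        assert len(sel) == len(expected)

    def test_enlarging_mask_never_shrinks_selection(self, grid16):
        rng = np.random.default_rng(5)
        t = Tractogram(streamlines=[rng.uniform(1, 14, size=(3, 3)) for _ in range(20)])
        small = np.zeros(grid16.shape, dtype=bool)
        small[5:7, 5:7, 5:7] = True
        big = small.copy()
        big[3:10, 3:10, 3:10] = True
        assert len(select_through_mask(t, small, grid16)) <= len(
            select_through_mask(t, big, grid16)
        )


class TestTractogramIO:
    @pytest.mark.parametrize("dialect", ["trk", "tck"])
    def test_empty_round_trip(self, tmp_path, grid16, dialect):
        path = tmp_path / f"empty.{dialect}"
        write_tractogram(Tractogram(), str(path), grid=grid16)
        assert len(read_tractogram(str(path))) == 0

    @pytest.mark.parametrize("dialect", ["trk", "tck"])
    def test_round_trip_preserves_coordinates(self, tmp_path, grid16, dialect):
        rng = np.random.default_rng(2)
        streamlines = [rng.uniform(0, 15, size=(5, 3)) for _ in range(3)]
        t = Tractogram(streamlines=streamlines)
        path = tmp_path / f"t.{dialect}"
        write_tractogram(t, str(path), grid=grid16)
        back = read_tractogram(str(path))
        assert len(back) == 3
        for a, b in zip(back, streamlines):
            assert np.allclose(a, b, atol=1e-5)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.trk"
        path.write_bytes(b"this is not a tractogram file at all")
        with pytest.raises(TractogramParseError):
            read_tractogram(str(path))

    def test_truncated_record_raises_parse_error(self, tmp_path, grid16):
        path = tmp_path / "t.tck"
        t = Tractogram(streamlines=[straight_streamline(5, 5)])
        write_tractogram(t, str(path), grid=grid16)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 10])
        with pytest.raises(TractogramParseError):
            read_tractogram(str(path))

    def test_unknown_extension_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_tractogram(str(tmp_path / "t.vtk"))


class TestVolumeIO:
    def test_binary_mask_round_trip(self, tmp_path, grid16):
        mask = np.zeros(grid16.shape, dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        path = tmp_path / "mask.nii"
        write_volume(mask, grid16.affine, str(path))
        back, affine = read_volume(str(path))
        assert np.array_equal(back.astype(bool), mask)
        assert np.allclose(affine, grid16.affine)

    def test_two_mm_affine_round_trip(self, tmp_path):
        g = TemplateGrid.isotropic(8, 2.0)
        vol = np.arange(8**3, dtype=np.float32).reshape(g.shape)
        path = tmp_path / "vol.nii"
        write_volume(vol, g.affine, str(path))
        back, affine = read_volume(str(path))
        assert np.allclose(back, vol)
        assert np.allclose(affine, g.affine)

    def test_four_dimensional_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_volume(np.zeros((4, 4, 4, 2)), np.eye(4), str(tmp_path / "x.nii"))


def test_streamline_validation():
    with pytest.raises(ValueError):
        Tractogram(streamlines=[np.array([[0.0, 0, 0]])])  # single point
    with pytest.raises(ValueError):
        Tractogram(streamlines=[np.array([[0.0, 0, 0], [0.0, 0, 0]])])  # duplicate
    with pytest.raises(ValueError):
        Tractogram(streamlines=[np.array([[0.0, 0, 0], [np.nan, 0, 0]])])
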