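import numpy as np
import pytest

from tractkit.grid import VolumeGrid
from tractkit.recon import DirectionField
from tractkit.tracking import (
    SeedError,
    Streamline,
    TrackingParams,
    Tractogram,
    default_params,
    filter_by_length,
    propagate,
    read_trk,
    seed_points,
    smooth_spline,
    track_whole_brain,
    write_trk,
)


def uniform_field(shape, direction, affine=None, n_dirs=1):
    """DirectionField with the same single direction in every voxel."""
    affine = np.eye(4) if affine is None else affine
    dirs = np.full(shape + (3, 3), np.nan)
    amps = np.full(shape + (3,), np.nan)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    for k in range(n_dirs):
        dirs[..., k, :] = d
        amps[..., k] = 1.0
    return DirectionField(dirs, amps, VolumeGrid(np.zeros(shape), affine))


def slab_mask(shape, affine=None):
    return VolumeGrid(np.ones(shape, np.uint8), np.eye(4) if affine is None else affine)


class TestSeedPoints:
    def test_seed_count_and_bounds_single_voxel(self):
        shape = (1, 1, 1)
        field = uniform_field(shape, (1, 0, 0))
        mask = slab_mask(shape)
        params = TrackingParams(step_size=0.5, seeds_per_voxel=5)
        seeds = seed_points(mask, field, params)
        assert len(seeds) == 5
        for p, d, vox, di in seeds:
            assert np.all(np.abs(p) <= 0.5 + 1e-12)  # inside the voxel cube
            assert vox == (0, 0, 0) and di == 0

    def test_two_maxima_double_the_seeds(self):
        shape = (2, 1, 1)
        field = uniform_field(shape, (1, 0, 0), n_dirs=2)
        params = TrackingParams(step_size=0.5, seeds_per_voxel=3)
        seeds = seed_points(slab_mask(shape), field, params)
        assert len(seeds) == 2 * 3 * 2

    def test_deterministic_per_seed(self):
        shape = (3, 3, 3)
        field = uniform_field(shape, (0, 1, 0))
        params = TrackingParams(step_size=0.5, seeds_per_voxel=4, rng_seed=11)
        a = seed_points(slab_mask(shape), field, params)
        b = seed_points(slab_mask(shape), field, params)
        assert all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))

    def test_voxels_without_maxima_yield_no_seeds(self):
        shape = (2, 1, 1)
        field = uniform_field(shape, (1, 0, 0))
        field.directions[1] = np.nan
        field.amplitudes[1] = np.nan
        seeds = seed_points(slab_mask(shape), field, TrackingParams(step_size=0.5, seeds_per_voxel=2))
        assert len(seeds) == 2
        assert all(s[2] == (0, 0, 0) for s in seeds)

    def test_empty_mask_rejected(self):
        shape = (2, 2, 2)
        field = uniform_field(shape, (1, 0, 0))
        empty = VolumeGrid(np.zeros(shape, np.uint8), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            seed_points(empty, field, TrackingParams(step_size=0.5))


class TestPropagate:
    def test_slab_endpoints_and_length(self):
        """Uniform +x field in an 11-voxel slab: track spans the slab."""
        shape = (11, 5, 5)
        field = uniform_field(shape, (1, 0, 0))
        mask = slab_mask(shape)
        params = TrackingParams(step_size=0.5, max_steps=500)
        seed = (np.array([5.0, 2.0, 2.0]), np.array([1.0, 0.0, 0.0]), (5, 2, 2), 0)
        sl = propagate(field, mask, seed, params)
        # voxel centres 0..10: mask spans [-0.5, 10.5]; one-step tolerance
        assert sl.points[:, 0].min() <= -0.5 + params.step_size + 1e-9
        assert sl.points[:, 0].max() >= 10.5 - params.step_size - 1e-9
        assert 9.0 <= sl.length() <= 11.0
        np.testing.assert_allclose(sl.points[:, 1], 2.0)

    def test_point_spacing_equals_step_size(self):
        shape = (11, 3, 3)
        field = uniform_field(shape, (1, 0, 0))
        params = TrackingParams(step_size=0.7, max_steps=100)
        sl = propagate(field, slab_mask(shape), (np.array([5.0, 1, 1]), np.array([1.0, 0, 0]), (5, 1, 1), 0), params)
        seg = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        np.testing.assert_allclose(seg, 0.7, atol=1e-6)

    def test_rotating_field_halts_at_curvature_constraint(self):
        """Direction rotates 90 degrees at x=5; 45-degree threshold halts there."""
        shape = (11, 11, 3)
        dirs = np.full(shape + (3, 3), np.nan)
        amps = np.full(shape + (3,), np.nan)
        dirs[:6, ..., 0, :] = (1.0, 0.0, 0.0)
        dirs[6:, ..., 0, :] = (0.0, 1.0, 0.0)
        amps[..., 0] = 1.0
        field = DirectionField(dirs, amps, VolumeGrid(np.zeros(shape), np.eye(4)))
        params = TrackingParams(step_size=0.5, angle_threshold=45.0, max_steps=200)
        seed = (np.array([2.0, 5.0, 1.0]), np.array([1.0, 0, 0]), (2, 5, 1), 0)
        sl = propagate(field, slab_mask(shape), seed, params)
        # forward half must stop within one step of the x=5.5 interface
        assert sl.points[:, 0].max() <= 5.5 + params.step_size + 1e-9
        assert sl.points[:, 0].max() >= 5.0 - params.step_size

    def test_no_step_angle_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        shape = (8, 8, 8)
        dirs = rng.normal(size=shape + (1, 3))
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        full = np.full(shape + (3, 3), np.nan)
        full[..., 0, :] = dirs[..., 0, :]
        amps = np.full(shape + (3,), np.nan)
        amps[..., 0] = 1.0
        field = DirectionField(full, amps, VolumeGrid(np.zeros(shape), np.eye(4)))
        params = TrackingParams(step_size=0.5, angle_threshold=50.0)
        t = track_whole_brain(field, slab_mask(shape), TrackingParams(step_size=0.5, angle_threshold=50.0, seeds_per_voxel=1))
        cos_t = np.cos(np.radians(50.0))
        for sl in t.streamlines:
            steps = np.diff(sl.points, axis=0)
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
            if len(steps) >= 2:
                assert np.all(np.einsum("ij,ij->i", steps[:-1], steps[1:]) >= cos_t - 1e-9)

    def test_seed_outside_mask_rejected(self):
        shape = (4, 4, 4)
        field = uniform_field(shape, (1, 0, 0))
        with pytest.raises(SeedError):
            propagate(field, slab_mask(shape), (np.array([40.0, 0, 0]), np.array([1.0, 0, 0]), (0, 0, 0), 0), TrackingParams(step_size=0.5))

    def test_crossing_followed_straight_through(self, crossing_phantom):
        """Seeded along bundle A, the track crosses bundle B without turning."""
        from tractkit.phantom import make_odf_field
        from tractkit.recon import extract_maxima
        from tractkit import connectome as cxn

        spec = crossing_phantom["spec"]
        odf = make_odf_field(spec)
        dirs = extract_maxima(odf)
        wm = crossing_phantom["wm"]
        params = default_params(wm, seeds_per_voxel=2)
        t = track_whole_brain(dirs, wm, params)
        t = filter_by_length(t, params.min_length, params.max_length)
        a = cxn.assign_endpoints(t, crossing_phantom["labels"], wm)
        pairs = {tuple(sorted(p)) for p in a.pairs[a.assigned]}
        assert pairs == {(1, 2), (3, 4)}  # never 1-3, 1-4, 2-3 or 2-4


class TestWholeBrain:
    def test_straight_phantom_connects_end_caps(self, straight_phantom, straight_directions):
        wm = straight_phantom["wm"]
        labels = straight_phantom["labels"].data
        params = default_params(wm, seeds_per_voxel=2)
        t = track_whole_brain(straight_directions, wm, params)
        assert len(t) > 0
        cap1 = np.argwhere(labels == 1)[:, 0].max()
        cap2 = np.argwhere(labels == 2)[:, 0].min()
        for sl in t.streamlines:
            xs = sl.points[:, 0] / 2.0  # voxel units
            assert xs.min() <= cap1 + 1.0 and xs.max() >= cap2 - 1.0

    def test_empty_field_empty_tractogram(self):
        shape = (3, 3, 3)
        dirs = np.full(shape + (3, 3), np.nan)
        amps = np.full(shape + (3,), np.nan)
        field = DirectionField(dirs, amps, VolumeGrid(np.zeros(shape), np.eye(4)))
        t = track_whole_brain(field, slab_mask(shape), TrackingParams(step_size=0.5, seeds_per_voxel=4))
        assert len(t) == 0

    def test_doubling_seeds_doubles_streamlines(self):
        shape = (9, 3, 3)
        field = uniform_field(shape, (1, 0, 0))
        t1 = track_whole_brain(field, slab_mask(shape), TrackingParams(step_size=0.5, seeds_per_voxel=2, rng_seed=1))
        t2 = track_whole_brain(field, slab_mask(shape), TrackingParams(step_size=0.5, seeds_per_voxel=4, rng_seed=1))
        assert len(t2) == 2 * len(t1)

    def test_bit_identical_for_fixed_seed(self, straight_phantom, straight_directions):
        wm = straight_phantom["wm"]
        params = default_params(wm, seeds_per_voxel=1, rng_seed=77)
        t1 = track_whole_brain(straight_directions, wm, params)
        t2 = track_whole_brain(straight_directions, wm, params)
        assert len(t1) == len(t2)
        for a, b in zip(t1.streamlines, t2.streamlines):
            np.testing.assert_array_equal(a.points, b.points)

    def test_points_stay_within_one_step_of_mask(self, curved_phantom, scheme30):
        from tractkit import recon

        wm = curved_phantom["wm"]
        tf = recon.fit_tensor(curved_phantom["dwi"], scheme30, wm)
        dirs = recon.extract_maxima(recon.tensor_to_odf(tf))
        params = default_params(wm, seeds_per_voxel=1)
        t = track_whole_brain(dirs, wm, params)
        m = wm.data.astype(bool)
        inv = np.linalg.inv(wm.affine)
        for sl in t.streamlines[::7]:
            ijk = np.rint(sl.points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            assert np.all(ijk >= 0) and np.all(ijk < m.shape)
            assert m[tuple(ijk.T)].all()


class TestFilterAndSmooth:
    def lines(self, lengths):
        out = []
        for L in lengths:
            n = max(2, int(L / 0.5) + 1)
            pts = np.column_stack([np.linspace(0, L, n), np.zeros(n), np.zeros(n)])
            out.append(Streamline(pts))
        return Tractogram(out, VolumeGrid(np.zeros((4, 4, 4)), np.eye(4)))

    def test_filter_counts(self):
        t = filter_by_length(self.lines([5, 20, 60]), 10, 50)
        assert len(t) == 1
        assert abs(t.streamlines[0].length() - 20) < 1e-9

    def test_filter_unbounded_is_identity(self):
        t0 = self.lines([5, 20, 60])
        t = filter_by_length(t0, 0, np.inf)
        assert len(t) == 3

    def test_filter_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        lengths = rng.uniform(1, 100, 40)
        t0 = self.lines(lengths)
        got = filter_by_length(t0, 25, 75)
        expect = [s for s in t0.streamlines if 25 <= s.length() <= 75]
        assert [id(s) for s in got.streamlines] == [id(s) for s in expect]

    def test_straight_line_is_spline_fixed_point(self):
        n = 80
        pts = np.column_stack([np.arange(n) * 0.5, np.full(n, 1.0), np.full(n, 2.0)])
        t = smooth_spline(Tractogram([Streamline(pts)], None), 4.0)
        assert np.abs(t.streamlines[0].points[:, 1] - 1.0).max() <= 1e-6
        assert np.abs(t.streamlines[0].points[:, 2] - 2.0).max() <= 1e-6

    def test_zigzag_deviation_reduced(self):
        n = 80
        pts = np.column_stack([np.arange(n) * 0.5, np.where(np.arange(n) % 2, 1.0, -1.0), np.zeros(n)])
        t = smooth_spline(Tractogram([Streamline(pts)], None), 6.0)
        assert np.abs(t.streamlines[0].points[:, 1]).max() < 1.0

    def test_endpoints_preserved_within_half_step(self):
        rng = np.random.default_rng(9)
        n = 60
        base = np.column_stack([np.arange(n) * 0.5, np.sin(np.arange(n) * 0.1), np.zeros(n)])
        t = smooth_spline(Tractogram([Streamline(base)], None), 4.0, step_size=0.5)
        for end in (0, -1):
            assert np.linalg.norm(t.streamlines[0].points[end] - base[end]) <= 0.25 + 1e-9

    def test_short_streamline_passed_through(self):
        pts = np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        t = smooth_spline(Tractogram([Streamline(pts)], None), 4.0)
        np.testing.assert_array_equal(t.streamlines[0].points, pts)


class TestTrkIO:
    def test_round_trip(self, tmp_path, straight_phantom, straight_directions):
        wm = straight_phantom["wm"]
        params = default_params(wm, seeds_per_voxel=1)
        t = track_whole_brain(straight_directions, wm, params)
        p = tmp_path / "t.trk"
        write_trk(t, p)
        back = read_trk(p)
        assert len(back) == len(t)
        for a, b in zip(t.streamlines, back.streamlines):
            np.testing.assert_allclose(a.points, b.points, atol=1e-4)
        np.testing.assert_allclose(back.grid.voxel_size, wm.voxel_size, atol=1e-5)
        assert back.grid.shape3 == wm.shape3


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step_size": 0.0},
            {"step_size": 1.0, "angle_threshold": 95.0},
            {"step_size": 1.0, "min_length": 50.0, "max_length": 10.0},
        ],
        ids=["zero-step", "angle-over-90", "min-over-max"],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrackingParams(**kwargs)

    def test_default_step_is_half_voxel(self):
        grid = VolumeGrid(np.zeros((4, 4, 4)), np.diag([1.0, 2.0, 3.0, 1.0]))
        assert default_params(grid).step_size == 0.5
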