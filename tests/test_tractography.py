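import numpy as np
import pytest

from salnet.grid import VoxelGrid
from salnet.synthetic_data import BundleSpec, gen_cohort, gen_parcellation, synthetic_grid
from salnet.tractography import (
    OrientationField, Streamline, TrackingParams, subject_connectome, track_one,
    two_roi_filter, whole_brain_track,
)

from conftest import make_uniform_field

PARAMS = TrackingParams(n_seeds=100, rng_seed=0)


class TestTrackOne:
    def test_uniform_field_straight_line(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 0, 0))
        sl = track_one(field, (0.3, 0.0, 0.0), PARAMS)
        assert sl is not None
        steps = np.diff(sl.points, axis=0)
        np.testing.assert_allclose(np.linalg.norm(steps, axis=1), 1.5, atol=1e-9)
        np.testing.assert_allclose(sl.points[:, 1:], 0.0, atol=1e-9)
        # spans the 40 mm mask up to one step at each end
        assert sl.points[:, 0].max() > grid1mm.voxel_to_mm((39.0, 0, 0))[0] - 2 * 1.5
        assert sl.points[:, 0].min() < grid1mm.voxel_to_mm((0.0, 0, 0))[0] + 2 * 1.5

    def test_90_degree_plane_halts(self, grid1mm):
        peaks = np.zeros(grid1mm.shape + (3, 3), dtype=np.float32)
        x_mm = grid1mm.voxel_centers_mm(np.argwhere(grid1mm.mask))[:, 0].reshape(grid1mm.shape)
        peaks[..., 0, :] = np.where((x_mm < 0)[..., None], (1.0, 0, 0), (0, 1.0, 0))
        field = OrientationField(grid=grid1mm, peaks=peaks)
        sl = track_one(field, (-10.0, 0.0, 0.0), PARAMS)
        # forward propagation must stop at the 90-degree plane (90 > 45)
        assert sl.points[:, 0].max() <= 1.5
        assert sl.points[:, 1].max() <= 1e-9

    def test_seed_outside_mask_none(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 0, 0))
        assert track_one(field, (500.0, 0.0, 0.0), PARAMS) is None

    def test_seed_without_peaks_none(self, grid1mm):
        peaks = np.zeros(grid1mm.shape + (1, 3), dtype=np.float32)
        field = OrientationField(grid=grid1mm, peaks=peaks)
        assert track_one(field, (0.0, 0.0, 0.0), PARAMS) is None

    def test_max_len_respected(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 0, 0))
        p = TrackingParams(n_seeds=1, max_len_mm=9.0, step_mm=1.5, min_len_mm=1.0)
        sl = track_one(field, (0.0, 0.0, 0.0), p)
        assert sl.length <= 9.0 + 1e-9

    def test_angle_invariant_along_streamline(self):
        field, grid = arc_field()
        sl = track_one(field, (0.0, 50.0, 0.0), PARAMS)
        segs = np.diff(sl.points, axis=0)
        segs /= np.linalg.norm(segs, axis=1, keepdims=True)
        cosines = (segs[:-1] * segs[1:]).sum(axis=1)
        assert np.all(np.degrees(np.arccos(np.clip(cosines, -1, 1))) <= 45.0 + 1e-6)


def arc_field(radius=50.0, half_width=4.0):
    """Tangent field of a circle of given radius in the x-y plane."""
    aff = np.eye(4)
    aff[:3, 3] = (-40.0, 10.0, -8.0)
    grid = VoxelGrid(shape=(80, 70, 16), affine=aff)
    idx = np.indices(grid.shape).reshape(3, -1).T
    mm = grid.voxel_to_mm(idx.astype(float))
    r = np.linalg.norm(mm[:, :2], axis=1)
    ang = np.degrees(np.arctan2(mm[:, 1], mm[:, 0]))
    in_tube = (np.abs(r - radius) <= half_width) & (np.abs(mm[:, 2]) <= half_width) \
        & (ang > 35) & (ang < 145)
    grid.mask = in_tube.reshape(grid.shape)
    peaks = np.zeros(grid.shape + (1, 3), dtype=np.float32)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.stack([-mm[:, 1], mm[:, 0], np.zeros(len(mm))], axis=1)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    t[~in_tube] = 0.0
    peaks[..., 0, :] = t.reshape(grid.shape + (3,))
    return OrientationField(grid=grid, peaks=peaks), grid


def analytic_tangent(p):
    t = np.array([-p[1], p[0], 0.0])
    return t / np.linalg.norm(t)


def reference_integration(grid, seed, direction, ds=0.01, max_len=400.0):
    """Fine-step integration of the continuous tangent field."""
    p = np.asarray(seed, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = int(max_len / ds)
    for _ in range(n):
        t = analytic_tangent(p)
        if t @ d < 0:
            t = -t
        p_new = p + ds * t
        if not grid.in_mask(p_new):
            break
        p, d = p_new, t
    return p


class TestArcOracle:
    def test_endpoints_match_fine_step_reference(self):
        field, grid = arc_field()
        params = TrackingParams(n_seeds=1, rng_seed=0)
        seed = np.array([0.0, 50.0, 0.0])
        sl = track_one(field, seed, params)
        assert sl is not None and sl.length > 40.0
        ref_fwd = reference_integration(grid, seed, (1.0, 0.0, 0.0))
        ref_bwd = reference_integration(grid, seed, (-1.0, 0.0, 0.0))
        ends = {tuple(np.round(sl.points[0], 3)), tuple(np.round(sl.points[-1], 3))}
        d_fwd = min(np.linalg.norm(np.array(e) - ref_fwd) for e in map(np.array, ends))
        d_bwd = min(np.linalg.norm(np.array(e) - ref_bwd) for e in map(np.array, ends))
        assert d_fwd <= 2 * params.step_mm
        assert d_bwd <= 2 * params.step_mm

    def test_straight_field_matches_reference_exactly(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 0, 0))
        sl = track_one(field, (0.0, 0.0, 0.0), PARAMS)
        # straight-line reference: endpoints on the seed line, same direction
        assert abs(sl.points[-1][0] - sl.points[0][0]) == pytest.approx(sl.length)


class TestWholeBrain:
    def test_zero_seeds_rejected(self):
        with pytest.raises(ValueError):
            TrackingParams(n_seeds=0)

    def test_determinism(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 1, 0))
        p = TrackingParams(n_seeds=200, rng_seed=42)
        a = whole_brain_track(field, p)
        b = whole_brain_track(field, p)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_empty_mask_errors(self):
        grid = VoxelGrid(shape=(4, 4, 4), affine=np.eye(4))
        field = make_uniform_field(grid, (1, 0, 0))
        field.grid.mask[:] = False
        with pytest.raises(ValueError):
            whole_brain_track(field, PARAMS)

    def test_translation_invariance(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 0.5, 0))
        p = TrackingParams(n_seeds=50, rng_seed=3)
        a = whole_brain_track(field, p)
        shifted_aff = grid1mm.affine.copy()
        shift = np.array([7.0, -11.0, 3.0])
        shifted_aff[:3, 3] += shift
        grid_b = VoxelGrid(shape=grid1mm.shape, affine=shifted_aff, mask=grid1mm.mask)
        field_b = OrientationField(grid=grid_b, peaks=field.peaks)
        b = whole_brain_track(field_b, p)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_allclose(sb.points, sa.points + shift, atol=1e-9)

    def test_length_bounds(self, grid1mm):
        field = make_uniform_field(grid1mm, (1, 0, 0))
        p = TrackingParams(n_seeds=300, rng_seed=1, max_len_mm=12.0, min_len_mm=3.0)
        for sl in whole_brain_track(field, p):
            assert 3.0 <= sl.length <= 12.0 + 1e-9

    def test_planted_bundle_retention_fraction(self):
        grid = synthetic_grid(1.0, (64, 48, 48))
        parc = gen_parcellation(grid, [
            ("A", "insular_opercular", (8.0, -12.0, 0.0), 6.0),
            ("B", "insular_opercular", (8.0, 12.0, 0.0), 6.0)])
        fields, _ = gen_cohort([BundleSpec(kind="straight", region_a="A", region_b="B",
                                           tube_radius_mm=2.5)], parc, 1, seed=0)
        field = fields[0]
        p = TrackingParams(n_seeds=20_000, rng_seed=5)
        retained = whole_brain_track(field, p)
        has_peak = np.linalg.norm(field.peaks, axis=-1).max(axis=-1) > 0.5
        frac_expected = has_peak.sum() / field.grid.mask.sum()
        frac = len(retained) / p.n_seeds
        assert frac == pytest.approx(frac_expected, rel=0.25)


def random_streamlines(rng, grid, n=100):
    out = []
    for _ in range(n):
        npts = rng.integers(2, 15)
        pts = rng.uniform(-14, 14, size=(npts, 3))
        out.append(Streamline(points=pts))
    return out


class TestTwoRoiFilter:
    def setup_rois(self, grid):
        roi_a = np.zeros(grid.shape, bool)
        roi_b = np.zeros(grid.shape, bool)
        roi_a[:8] = True
        roi_b[-8:] = True
        return roi_a, roi_b

    def test_no_streamlines(self, grid1mm):
        roi_a, roi_b = self.setup_rois(grid1mm)
        assert two_roi_filter([], roi_a, roi_b, grid1mm) == 0

    def test_single_connecting_streamline_and_exclusion(self, grid1mm):
        roi_a, roi_b = self.setup_rois(grid1mm)
        pts = np.array([(-15.0, 0, 0), (0.0, 0, 0), (15.0, 0, 0)])
        sl = Streamline(points=pts)
        assert two_roi_filter([sl], roi_a, roi_b, grid1mm) == 1
        excl = np.zeros(grid1mm.shape, bool)
        excl[grid1mm.nearest_voxel((0.0, 0.0, 0.0))] = True
        assert two_roi_filter([sl], roi_a, roi_b, grid1mm, exclusions=[excl]) == 0

    def test_overlapping_rois_error(self, grid1mm):
        roi = np.ones(grid1mm.shape, bool)
        with pytest.raises(ValueError, match="overlap"):
            two_roi_filter([], roi, roi, grid1mm)

    def test_random_streamlines_match_endpoint_oracle(self, grid1mm):
        rng = np.random.default_rng(8)
        roi_a, roi_b = self.setup_rois(grid1mm)
        sls = random_streamlines(rng, grid1mm)
        expected = 0
        for sl in sls:
            va = grid1mm.nearest_voxel(sl.points[0])
            vb = grid1mm.nearest_voxel(sl.points[-1])
            if va is None or vb is None:
                continue
            if (roi_a[va] and roi_b[vb]) or (roi_a[vb] and roi_b[va]):
                expected += 1
        assert two_roi_filter(sls, roi_a, roi_b, grid1mm) == expected


@pytest.fixture(scope="module")
def planted():
    grid = synthetic_grid(1.0, (64, 48, 48))
    parc = gen_parcellation(grid, [
        ("A", "insular_opercular", (8.0, -12.0, 0.0), 6.0),
        ("B", "insular_opercular", (8.0, 12.0, 0.0), 6.0),
        ("C", "middle_cingulate", (8.0, 0.0, 14.0), 6.0)])
    fields, _ = gen_cohort([BundleSpec(kind="straight", region_a="A", region_b="B",
                                       tube_radius_mm=2.5)], parc, 1, seed=1)
    return fields[0], parc


class TestSubjectConnectome:

    def test_planted_pair_only(self, planted):
        field, parc = planted
        con = subject_connectome(field, parc, TrackingParams(n_seeds=10_000, rng_seed=2), "s0")
        assert con.count("A", "B", "L") > 0
        assert con.count("A", "B", "R") > 0
        for pair in (("A", "C"), ("B", "C")):
            for h in ("L", "R"):
                assert con.count(*pair, h) == 0

    def test_symmetry(self, planted):
        field, parc = planted
        con = subject_connectome(field, parc, TrackingParams(n_seeds=5_000, rng_seed=2), "s0")
        assert con.count("A", "B", "L") == con.count("B", "A", "L")

    def test_seed_scaling(self, planted):
        field, parc = planted
        c1 = subject_connectome(field, parc, TrackingParams(n_seeds=10_000, rng_seed=7), "s")
        c2 = subject_connectome(field, parc, TrackingParams(n_seeds=20_000, rng_seed=7), "s")
        n1 = c1.count("A", "B", "L") + c1.count("A", "B", "R")
        n2 = c2.count("A", "B", "L") + c2.count("A", "B", "R")
        assert n2 / n1 == pytest.approx(2.0, rel=0.2)

    def test_requires_two_regions(self, grid1mm):
        from salnet.parcel_select import ParcellationVolume
        labels = np.zeros(grid1mm.shape, int)
        labels[0, 0, 0] = 1
        parc = ParcellationVolume(grid=grid1mm, labels=labels, name_map={1: "L_A"})
        field = make_uniform_field(grid1mm, (1, 0, 0))
        with pytest.raises(ValueError):
            subject_connectome(field, parc, PARAMS)
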