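"""Detection, the intensity-window co-localisation rule, density, soma area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomquant.errors import (
    DegenerateGeometryError,
    EmptyInputError,
    MissingChannelError,
    UnevaluablePunctumError,
    ValidationError,
)
from glomquant.puncta_coloc import (
    ColocCall,
    ColocParams,
    DetectedPunctum,
    DetectionParams,
    coloc_classify,
    coloc_percentage,
    detect_puncta,
    match_to_ground_truth,
    max_projection,
    puncta_density,
    restrict_to_cell,
    soma_area,
)
from glomquant.synth_imaging import (
    NOISELESS,
    FilamentSet,
    GroundTruthPunctum,
    ImagingVolume,
    RenderParams,
    VoxelGrid,
    render_scene,
)


def _row_volume(target_row, punctum_row=None, ny=3, nz=1):
    """Volume whose (z=0, y=1) x-row carries the given 1D profiles."""
    nx = len(target_row)
    tgt = np.zeros((nz, ny, nx))
    tgt[0, 1, :] = target_row
    src = np.zeros((nz, ny, nx))
    src[0, 1, :] = punctum_row if punctum_row is not None else target_row
    grid = VoxelGrid(shape_zyx=(nz, ny, nx), voxel_size_xy=0.05, voxel_size_z=0.37)
    return ImagingVolume(grid=grid, channels={"vGAT": tgt, "mRuby": src})


def _punctum_at(x_um, diameter=0.5):
    return DetectedPunctum(
        centroid_xyz=np.array([x_um, 1 * 0.05, 0.0]),
        quality=1.0,
        x_extent=(x_um - diameter / 2, x_um + diameter / 2),
    )


class TestDetect:
    def test_all_zero_volume_empty(self):
        grid = VoxelGrid(shape_zyx=(3, 64, 64))
        vol = ImagingVolume(grid=grid, channels={"mRuby": np.zeros((3, 64, 64))})
        assert detect_puncta(vol, DetectionParams()) == []

    def test_missing_channel_raises(self):
        grid = VoxelGrid(shape_zyx=(3, 32, 32))
        vol = ImagingVolume(grid=grid, channels={"GFP": np.zeros((3, 32, 32))})
        with pytest.raises(MissingChannelError):
            detect_puncta(vol, DetectionParams(channel="mRuby"))

    def test_isolated_puncta_recovered_within_one_voxel(self):
        grid = VoxelGrid(shape_zyx=(4, 500, 500))
        fil = FilamentSet([np.array([[1.0, 8.25, 0.555], [15.0, 8.25, 0.555]])])
        xs = [2.0, 5.0, 8.0, 11.0, 14.0]
        pts = [GroundTruthPunctum(np.array([x, 8.25, 0.555])) for x in xs]
        vol = render_scene(grid, fil, pts, NOISELESS, RenderParams(distractor_density_per_um3=0))
        det = detect_puncta(vol, DetectionParams())
        assert len(det) == 5
        tol = np.array([grid.voxel_size_xy, grid.voxel_size_xy, grid.voxel_size_z])
        for p in pts:
            best = min(det, key=lambda d: np.linalg.norm(d.centroid_xyz - p.centroid_xyz))
            assert np.all(np.abs(best.centroid_xyz - p.centroid_xyz) <= tol + 1e-9)

    def test_count_monotone_in_quality_threshold(self, noisy_scene):
        thresholds = [0.0, 100.0, 300.0, 800.0, 2000.0, 1e9]
        counts = [
            len(detect_puncta(noisy_scene.volume, DetectionParams(quality_threshold=t)))
            for t in thresholds
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_detections_sorted_by_quality_and_above_threshold(self, noisy_scene):
        params = DetectionParams(quality_threshold=300.0)
        det = detect_puncta(noisy_scene.volume, params)
        qs = [d.quality for d in det]
        assert qs == sorted(qs, reverse=True)
        assert all(q >= params.quality_threshold for q in qs)

    def test_default_snr_recall_precision(self, noisy_scene):
        det = detect_puncta(noisy_scene.volume, DetectionParams())
        m = match_to_ground_truth(det, noisy_scene.puncta, radius_um=0.5)
        assert m.recall >= 0.9 and m.precision >= 0.9


class TestRestrictToCell:
    def test_zero_threshold_keeps_all_with_background(self, noisy_scene):
        det = detect_puncta(noisy_scene.volume, DetectionParams())
        kept = restrict_to_cell(det, noisy_scene.volume, overlap_threshold=0.0)
        assert kept == det

    def test_threshold_above_max_empties(self, noisy_scene):
        det = detect_puncta(noisy_scene.volume, DetectionParams())
        hi = float(noisy_scene.volume.channels["GFP"].max()) + 1
        assert restrict_to_cell(det, noisy_scene.volume, overlap_threshold=hi) == []

    def test_off_cell_punctum_excluded(self):
        grid = VoxelGrid(shape_zyx=(4, 400, 400))
        fil = FilamentSet([np.array([[1.0, 2.0, 0.555], [12.0, 2.0, 0.555]])])
        on = GroundTruthPunctum(np.array([5.0, 2.0, 0.555]))
        off = GroundTruthPunctum(np.array([5.0, 9.0, 0.555]))  # 7 um off the filament
        vol = render_scene(grid, fil, [on, off], NOISELESS, RenderParams(distractor_density_per_um3=0))
        det = detect_puncta(vol, DetectionParams())
        assert len(det) == 2
        kept = restrict_to_cell(det, vol, overlap_threshold=10.0)
        assert len(kept) == 1
        assert abs(kept[0].centroid_xyz[1] - 2.0) < 0.2


class TestColocClassify:
    def test_zero_target_channel_not_coloc(self):
        vol = _row_volume(np.zeros(200), punctum_row=np.r_[np.zeros(95), 50 * np.ones(10), np.zeros(95)])
        call = coloc_classify(vol, _punctum_at(5.0))
        assert call.center_mean == 0 and call.background_mean == 0 and call.background_sd == 0
        assert call.is_coloc is False  # strict inequality fails at 0 > 0

    def test_elevated_centre_over_noisy_background(self):
        rng = np.random.default_rng(0)
        row = rng.normal(100, 10, size=400)
        c = 200  # centre voxel
        half = int(round(1.0 / 0.05 / 2))
        row[c - half : c + half + 1] = 200.0
        src = np.zeros(400)
        src[c] = 1.0
        call = coloc_classify(_row_volume(row, src), _punctum_at(c * 0.05))
        assert call.is_coloc is True
        assert call.center_mean == pytest.approx(200.0)

    def test_centre_equal_to_background_mean_not_coloc(self):
        row = np.full(400, 100.0)
        call = coloc_classify(_row_volume(row), _punctum_at(10.0))
        assert call.center_mean == pytest.approx(call.background_mean)
        assert call.is_coloc is False

    def test_criterion_matches_direct_evaluation(self):
        """ColocCall invariant: is_coloc <=> centre > bg + m x sd, recomputed by hand."""
        rng = np.random.default_rng(5)
        row = rng.normal(50, 5, size=400)
        vol = _row_volume(row)
        p = _punctum_at(10.0)
        call = coloc_classify(vol, p, params=ColocParams(sd_multiplier=1.0))
        vx = 0.05
        lo = int(round(p.x_extent[0] / vx))
        hi = int(round(p.x_extent[1] / vx))
        m = lo + int(np.argmax(row[lo : hi + 1]))
        halfw = int(round(1.0 / vx / 2))
        centre = row[m - halfw : m + halfw + 1].mean()
        bgw = int(round(1.0 / vx))
        bg = np.r_[row[lo - bgw : lo], row[hi + 1 : hi + 1 + bgw]]
        assert call.center_mean == pytest.approx(centre)
        assert call.background_mean == pytest.approx(bg.mean())
        assert call.is_coloc == (centre > bg.mean() + bg.std(ddof=1))

    def test_both_flanks_out_of_bounds_unevaluable(self):
        row = np.full(20, 10.0)
        vol = _row_volume(row)
        p = DetectedPunctum(np.array([0.5, 0.05, 0.0]), 1.0, (-1.0, 2.0))
        with pytest.raises(UnevaluablePunctumError):
            coloc_classify(vol, p)

    @settings(deadline=None, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 100))
    def test_scale_equivariance(self, scale, seed):
        """Multiplying both channels by c > 0 leaves every call unchanged."""
        rng = np.random.default_rng(seed)
        row = rng.uniform(10, 200, size=300)
        src = rng.uniform(0, 50, size=300)
        a = coloc_classify(_row_volume(row, src), _punctum_at(7.0))
        b = coloc_classify(_row_volume(row * scale, src * scale), _punctum_at(7.0))
        assert a.is_coloc == b.is_coloc


class TestColocPercentage:
    def _calls(self, flags):
        return [ColocCall(i, 0, 0, 0, f) for i, f in enumerate(flags)]

    def test_printed_tally(self):
        s = coloc_percentage(self._calls([True] * 39 + [False] * 14))
        assert s.n_coloc == 39 and s.n_total == 53
        assert s.percent == pytest.approx(100 * 39 / 53)
        assert round(s.percent) == 74

    def test_all_true_and_none_true(self):
        assert coloc_percentage(self._calls([True] * 7)).percent == 100.0
        assert coloc_percentage(self._calls([False] * 9)).percent == 0.0

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            coloc_percentage([])


class TestDensity:
    def test_zero_matched(self, straight_filament):
        res = puncta_density([], straight_filament)
        assert res.n_puncta == 0 and res.density == 0.0

    def test_forced_arithmetic(self):
        fil = FilamentSet([np.array([[0, 0, 0], [50.0, 0, 0]])])
        pts = [GroundTruthPunctum(np.array([5.0 * i, 0.1, 0.0])) for i in range(10)]
        res = puncta_density(pts, fil, match_radius=0.5)
        assert res.total_length == pytest.approx(50.0)
        assert res.n_puncta == 10
        assert res.density == pytest.approx(0.2)

    def test_far_puncta_not_counted(self):
        fil = FilamentSet([np.array([[0, 0, 0], [50.0, 0, 0]])])
        pts = [GroundTruthPunctum(np.array([25.0, 3.0, 0.0]))]
        assert puncta_density(pts, fil).n_puncta == 0

    def test_degenerate_geometry_raises(self):
        fil = FilamentSet([np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])])
        with pytest.raises(DegenerateGeometryError):
            puncta_density([], fil)

    def test_placement_level_unbiased_over_seeds(self):
        """Mean estimated density over 200 seeds within 2 SE of truth."""
        from glomquant.synth_imaging import generate_filaments, place_puncta

        grid = VoxelGrid(shape_zyx=(4, 1200, 1200))
        ests = []
        for s in range(200):
            fil = generate_filaments(grid, 1, 100.0, seed=s)
            pts = place_puncta(fil, density=0.19, coloc_fraction=0.5, seed=1000 + s)
            ests.append(puncta_density(pts, fil, match_radius=0.5).density)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.19) <= 2 * se


class TestProjectionAndSoma:
    def test_single_plane_identity(self):
        grid = VoxelGrid(shape_zyx=(1, 8, 8))
        img = np.random.default_rng(0).uniform(size=(1, 8, 8))
        vol = ImagingVolume(grid=grid, channels={"GFP": img})
        np.testing.assert_array_equal(max_projection(vol, "GFP"), img[0])

    def test_dominant_plane_wins(self):
        grid = VoxelGrid(shape_zyx=(2, 5, 5))
        a = np.random.default_rng(1).uniform(size=(5, 5))
        vol = ImagingVolume(grid=grid, channels={"c": np.stack([a, a + 10])})
        np.testing.assert_array_equal(max_projection(vol, "c"), a + 10)

    def test_projection_dominates_every_plane(self):
        grid = VoxelGrid(shape_zyx=(6, 12, 12))
        img = np.random.default_rng(2).uniform(size=(6, 12, 12))
        proj = max_projection(ImagingVolume(grid=grid, channels={"c": img}), "c")
        assert np.all(proj[None, :, :] >= img)

    @pytest.mark.parametrize(
        "poly,area",
        [
            ([(0, 0), (10, 0), (10, 10), (0, 10)], 100.0),
            ([(0, 0), (4, 0), (0, 3)], 6.0),
        ],
    )
    def test_soma_area_known_polygons(self, poly, area):
        assert soma_area(np.array(poly, dtype=float)) == pytest.approx(area)

    def test_soma_area_matches_monte_carlo(self):
        """Random star-convex 12-gon vs rejection-sampling point-in-polygon."""
        from matplotlib.path import Path

        rng = np.random.default_rng(12)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(3, 10, 12)
        verts = np.c_[rad * np.cos(ang), rad * np.sin(ang)]
        area = soma_area(verts)
        path = Path(verts)
        n = 400_000
        pts = rng.uniform(-10, 10, size=(n, 2))
        mc = path.contains_points(pts).mean() * 400.0
        assert abs(area - mc) / mc < 0.01

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValidationError):
            soma_area(np.array([(0.0, 0.0), (1.0, 1.0)]))
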