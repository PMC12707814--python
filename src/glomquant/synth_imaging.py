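"""Synthetic two-channel confocal scenes with known ground truth.

Generates dendrite-like polylines inside a voxel grid, scatters presynaptic
puncta along them with per-punctum co-localisation labels, and renders a
three-channel stack ("GFP" cell fill, "mRuby" presynaptic marker, "vGAT"
GABAergic marker) under a Gaussian-PSF / Poisson-noise optics model.  Every
stochastic operation takes an explicit seed; there is no global RNG state.

Conventions
-----------
Physical coordinates are micrometres, (x, y, z) order, with the origin at the
centre of voxel (0, 0, 0).  Arrays are stored (z, y, x), x fastest.  Default
voxel sizes follow high-NA confocal acquisition: 0.033 µm in xy and 0.37 µm
z steps; co-localisation stacks are thin (3–4 planes, 1.1–1.5 µm total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import geometry
from .errors import InfeasibleGeometryError, ValidationError

#: FWHM-to-sigma conversion for a Gaussian profile.
FWHM_TO_SIGMA = 1.0 / 2.355


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel lattice with physical calibration.

    ``shape_zyx`` is the array shape; ``voxel_size_xy`` and ``voxel_size_z``
    are edge lengths in µm.  The physical extent along x is
    ``(nx - 1) * voxel_size_xy`` (origin at the first voxel centre).
    """

    shape_zyx: tuple[int, int, int]
    voxel_size_xy: float = 0.033
    voxel_size_z: float = 0.37

    def __post_init__(self):
        if len(self.shape_zyx) != 3 or any(int(s) < 1 for s in self.shape_zyx):
            raise ValidationError("shape_zyx must be three integers >= 1")
        if self.voxel_size_xy <= 0 or self.voxel_size_z <= 0:
            raise ValidationError("voxel sizes must be > 0")

    @property
    def extent_xyz(self) -> tuple[float, float, float]:
        """Physical span (µm) covered by voxel centres, (x, y, z)."""
        nz, ny, nx = self.shape_zyx
        return (
            (nx - 1) * self.voxel_size_xy,
            (ny - 1) * self.voxel_size_xy,
            (nz - 1) * self.voxel_size_z,
        )

    def voxel_sizes_xyz(self) -> np.ndarray:
        return np.array([self.voxel_size_xy, self.voxel_size_xy, self.voxel_size_z])

    def um_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) µm -> fractional voxel indices (z, y, x)."""
        xyz = np.asarray(xyz, dtype=float)
        return np.stack(
            [
                xyz[..., 2] / self.voxel_size_z,
                xyz[..., 1] / self.voxel_size_xy,
                xyz[..., 0] / self.voxel_size_xy,
            ],
            axis=-1,
        )

    def contains(self, xyz: np.ndarray) -> bool:
        ex, ey, ez = self.extent_xyz
        x, y, z = np.asarray(xyz, dtype=float)
        return 0 <= x <= ex and 0 <= y <= ey and 0 <= z <= ez


@dataclass
class FilamentSet:
    """Traced dendrite polylines for one cell (µm, (x, y, z) points)."""

    polylines: list[np.ndarray]
    cell_id: str = "cell0"

    def __post_init__(self):
        self.polylines = [np.asarray(p, dtype=float) for p in self.polylines]
        for p in self.polylines:
            if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 3:
                raise ValidationError("each polyline needs >= 2 points of (x, y, z)")

    @property
    def total_length(self) -> float:
        return geometry.total_length(self.polylines)


@dataclass
class GroundTruthPunctum:
    """A simulated presynaptic punctum with its true co-localisation label."""

    centroid_xyz: np.ndarray
    diameter: float = 0.5
    amplitude: float = 150.0
    coloc_label: bool = False
    parent_polyline: int | None = None

    def __post_init__(self):
        self.centroid_xyz = np.asarray(self.centroid_xyz, dtype=float)
        if self.diameter <= 0:
            raise ValidationError("diameter must be > 0")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")


@dataclass(frozen=True)
class OpticsNoiseModel:
    """Gaussian-PSF blur plus photon (Poisson) and read (Gaussian) noise.

    Stand-in for confocal acquisition: no optical sectioning physics beyond
    the anisotropic Gaussian PSF, no spectral bleed-through.
    """

    psf_sigma_xy: float = 0.10
    psf_sigma_z: float = 0.30
    background_level: float = 10.0
    photon_noise: bool = True
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValidationError("PSF sigmas must be > 0")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")


NOISELESS = OpticsNoiseModel(background_level=0.0, photon_noise=False, read_noise_sd=0.0)


@dataclass
class ImagingVolume:
    """Named multichannel 3D stack on a common voxel grid."""

    grid: VoxelGrid
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        for name, arr in self.channels.items():
            if tuple(arr.shape) != tuple(self.grid.shape_zyx):
                raise ValidationError(f"channel {name!r} shape {arr.shape} != grid")


@dataclass
class RenderParams:
    """Knobs of the scene renderer that are not per-punctum properties."""

    gfp_amplitude: float = 100.0
    tube_radius_um: float = 0.15
    vgat_amplitude: float = 150.0
    coloc_offset_sd_um: float = 0.05
    distractor_density_per_um3: float = 0.05
    distractor_min_dist_um: float = 0.5
    distractor_diameter_um: float = 0.5


@dataclass
class GroundTruthScene:
    """A rendered scene bundled with everything needed to score an analysis."""

    grid: VoxelGrid
    filaments: FilamentSet
    puncta: list[GroundTruthPunctum]
    volume: ImagingVolume | None = None
    jitter_um: float = 0.1
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filament generation


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi] (single bounce is enough for small steps)."""
    if value < lo:
        return lo + (lo - value)
    if value > hi:
        return hi - (value - hi)
    return value


def _walk_polyline(
    rng: np.random.Generator,
    length: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    start: np.ndarray,
    step_um: float,
    turn_sd: float = 0.35,
) -> np.ndarray:
    """Correlated random walk of fixed step length inside a box.

    The walk lives mostly in the xy plane (dendrites in thin stacks); z drifts
    slowly within its bounds.  Segment lengths are exactly ``step_um`` in xy
    projection plus a small z component, so the polyline length is controlled.
    """
    n_steps = max(1, int(round(length / step_um)))
    theta = rng.uniform(0, 2 * np.pi)
    z_span = bounds_hi[2] - bounds_lo[2]
    pts = [start.copy()]
    p = start.copy()
    for _ in range(n_steps):
        theta += rng.normal(0.0, turn_sd)
        dz = rng.normal(0.0, 0.03 * z_span) if z_span > 0 else 0.0
        # keep total step length = step_um
        dxy = np.sqrt(max(step_um**2 - dz**2, 1e-12))
        cand = p + np.array([dxy * np.cos(theta), dxy * np.sin(theta), dz])
        for ax in range(3):
            if cand[ax] < bounds_lo[ax] or cand[ax] > bounds_hi[ax]:
                cand[ax] = _reflect(cand[ax], bounds_lo[ax], bounds_hi[ax])
                if ax < 2:  # bounce the heading off the wall
                    theta = np.pi - theta if ax == 0 else -theta
        cand = np.clip(cand, bounds_lo, bounds_hi)
        pts.append(cand)
        p = cand
    return np.vstack(pts)


def generate_filaments(
    grid: VoxelGrid,
    n_branches: int = 0,
    target_length: float = 100.0,
    seed: int = 0,
    step_um: float = 0.5,
    margin_um: float = 0.5,
    cell_id: str = "cell0",
) -> FilamentSet:
    """Generate a dendrite-like filament set of approximately ``target_length`` µm.

    One main polyline plus ``n_branches`` branches rooted on it, each a
    correlated random walk with fixed step length, so the summed segment
    length is within 10% of the target.  Deterministic for a fixed seed.

    Raises
    ------
    InfeasibleGeometryError
        If the target length cannot plausibly be packed into the grid extent.
    """
    if target_length <= 0:
        raise ValidationError("target_length must be > 0")
    if n_branches < 0:
        raise ValidationError("n_branches must be >= 0")
    ex, ey, ez = grid.extent_xyz
    lo = np.array([margin_um, margin_um, min(margin_um, ez / 4 if ez > 0 else 0.0)])
    hi = np.array([ex - lo[0], ey - lo[1], ez - lo[2]])
    if np.any(hi <= lo[:2].min()) or hi[0] <= lo[0] or hi[1] <= lo[1]:
        raise InfeasibleGeometryError("grid too small for the walk margin")
    # packing heuristic: a tube of ~2*step width cannot exceed ~half the slab area
    capacity = 0.5 * (hi[0] - lo[0]) * (hi[1] - lo[1]) / step_um
    if target_length > capacity:
        raise InfeasibleGeometryError(
            f"target_length {target_length:.1f} µm exceeds grid capacity "
            f"~{capacity:.1f} µm"
        )
    rng = np.random.default_rng(seed)
    per = target_length / (n_branches + 1)
    start = rng.uniform(lo, hi)
    main = _walk_polyline(rng, per, lo, hi, start, step_um)
    polylines = [main]
    for _ in range(n_branches):
        root = main[rng.integers(0, len(main))]
        polylines.append(_walk_polyline(rng, per, lo, hi, root.copy(), step_um))
    return FilamentSet(polylines=polylines, cell_id=cell_id)


# ---------------------------------------------------------------------------
# punctum placement


def place_puncta(
    filaments: FilamentSet,
    density: float = 0.19,
    coloc_fraction: float = 0.74,
    seed: int = 0,
    jitter_um: float = 0.1,
    grid: VoxelGrid | None = None,
    n_exact: int | None = None,
    diameter: float = 0.5,
    amplitude: float = 150.0,
) -> list[GroundTruthPunctum]:
    """Scatter puncta along filaments at a linear density (µm⁻¹).

    The punctum count is Poisson with mean ``density × total_length`` (or
    ``n_exact`` if given); positions are arclength-uniform with isotropic
    jitter inside a ball of radius ``jitter_um``; each ``coloc_label`` is an
    independent Bernoulli(``coloc_fraction``) draw.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValidationError("coloc_fraction must be in [0, 1]")
    if density < 0:
        raise ValidationError("density must be >= 0")
    rng = np.random.default_rng(seed)
    L = filaments.total_length
    n = int(rng.poisson(density * L)) if n_exact is None else int(n_exact)
    lengths = np.array([geometry.polyline_length(p) for p in filaments.polylines])
    cum = np.cumsum(lengths)
    puncta: list[GroundTruthPunctum] = []
    for _ in range(n):
        s = rng.uniform(0.0, L)
        j = int(np.searchsorted(cum, s, side="right"))
        j = min(j, len(lengths) - 1)
        local_s = s - (cum[j] - lengths[j])
        base = geometry.point_at_arclength(filaments.polylines[j], local_s)
        # uniform in a ball of radius jitter_um
        while True:
            off = rng.uniform(-jitter_um, jitter_um, size=3)
            if np.dot(off, off) <= jitter_um**2:
                break
        pos = base + off
        if grid is not None:
            ex, ey, ez = grid.extent_xyz
            pos = np.clip(pos, 0.0, [ex, ey, ez])
        puncta.append(
            GroundTruthPunctum(
                centroid_xyz=pos,
                diameter=diameter,
                amplitude=amplitude,
                coloc_label=bool(rng.uniform() < coloc_fraction),
                parent_polyline=j,
            )
        )
    return puncta


# ---------------------------------------------------------------------------
# rendering


def _add_gaussian_blob(
    arr: np.ndarray,
    grid: VoxelGrid,
    center_xyz: np.ndarray,
    sigma_xy_um: float,
    sigma_z_um: float,
    amplitude: float,
    support_sigmas: float = 4.0,
) -> None:
    """Accumulate an anisotropic Gaussian blob (peak = amplitude) in place."""
    nz, ny, nx = arr.shape
    cz, cy, cx = grid.um_to_voxel(np.asarray(center_xyz, dtype=float))
    sx = sigma_xy_um / grid.voxel_size_xy
    sz = sigma_z_um / grid.voxel_size_z
    rz = max(1, int(np.ceil(support_sigmas * sz)))
    rxy = max(1, int(np.ceil(support_sigmas * sx)))
    z0, z1 = max(0, int(cz) - rz), min(nz, int(cz) + rz + 2)
    y0, y1 = max(0, int(cy) - rxy), min(ny, int(cy) + rxy + 2)
    x0, x1 = max(0, int(cx) - rxy), min(nx, int(cx) + rxy + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    gz = np.exp(-0.5 * ((np.arange(z0, z1) - cz) / sz) ** 2)
    gy = np.exp(-0.5 * ((np.arange(y0, y1) - cy) / sx) ** 2)
    gx = np.exp(-0.5 * ((np.arange(x0, x1) - cx) / sx) ** 2)
    arr[z0:z1, y0:y1, x0:x1] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def blob_sigmas_um(diameter: float, optics: OpticsNoiseModel) -> tuple[float, float]:
    """Effective blob sigmas: punctum size convolved with the PSF (µm)."""
    s0 = diameter * FWHM_TO_SIGMA
    return (
        float(np.hypot(s0, optics.psf_sigma_xy)),
        float(np.hypot(s0, optics.psf_sigma_z)),
    )


def render_scene(
    grid: VoxelGrid,
    filaments: FilamentSet,
    puncta: list[GroundTruthPunctum],
    optics: OpticsNoiseModel = OpticsNoiseModel(),
    params: RenderParams | None = None,
) -> ImagingVolume:
    """Render the three-channel stack for a ground-truth scene.

    "mRuby" holds one anisotropic Gaussian blob per punctum; "vGAT" holds
    blobs at coloc-labelled puncta (with a small placement offset) plus
    off-filament distractor blobs; "GFP" renders the filament tubes.  Noise
    (background, Poisson, read) is applied last, deterministically per
    ``optics.seed``.
    """
    params = params or RenderParams()
    for p in puncta:
        if not grid.contains(p.centroid_xyz):
            raise ValidationError(f"punctum at {p.centroid_xyz} outside grid extent")
    shape = tuple(grid.shape_zyx)
    mruby = np.zeros(shape, dtype=float)
    vgat = np.zeros(shape, dtype=float)
    gfp = np.zeros(shape, dtype=float)
    rng = np.random.default_rng(optics.seed)

    for p in puncta:
        sxy, sz = blob_sigmas_um(p.diameter, optics)
        _add_gaussian_blob(mruby, grid, p.centroid_xyz, sxy, sz, p.amplitude)

    # GFP filament tubes: splat dense centreline samples, blur to tube radius
    dense: list[np.ndarray] = []
    spacing = grid.voxel_size_xy / 2.0
    for poly in filaments.polylines:
        dense.append(geometry.resample_polyline(poly, spacing))
    if dense:
        all_pts = np.vstack(dense)
        idx = np.round(grid.um_to_voxel(all_pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        np.add.at(gfp, tuple(idx[ok].T), 1.0)
        sig_xy = np.hypot(params.tube_radius_um, optics.psf_sigma_xy) / grid.voxel_size_xy
        sig_z = np.hypot(params.tube_radius_um, optics.psf_sigma_z) / grid.voxel_size_z
        gfp = ndimage.gaussian_filter(gfp, sigma=(sig_z, sig_xy, sig_xy))
        peak = gfp.max()
        if peak > 0:
            gfp *= params.gfp_amplitude / peak
        tree = cKDTree(all_pts)
    else:
        tree = None

    # vGAT: at co-localised puncta (small offset), plus off-filament distractors
    dxy, dz = blob_sigmas_um(params.distractor_diameter_um, optics)
    for p in puncta:
        if p.coloc_label:
            off = rng.normal(0.0, params.coloc_offset_sd_um, size=3)
            _add_gaussian_blob(vgat, grid, p.centroid_xyz + off, dxy, dz, params.vgat_amplitude)
    ex, ey, ez = grid.extent_xyz
    volume_um3 = max(ex, grid.voxel_size_xy) * max(ey, grid.voxel_size_xy) * max(ez, grid.voxel_size_z)
    n_distr = int(rng.poisson(params.distractor_density_per_um3 * volume_um3))
    for _ in range(n_distr):
        for _try in range(20):
            pos = rng.uniform([0, 0, 0], [ex, ey, max(ez, 1e-6)])
            if tree is None or tree.query(pos)[0] >= params.distractor_min_dist_um:
                _add_gaussian_blob(vgat, grid, pos, dxy, dz, params.vgat_amplitude)
                break

    channels = {"GFP": gfp, "mRuby": mruby, "vGAT": vgat}
    for name in sorted(channels):
        img = channels[name] + optics.background_level
        if optics.photon_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)
    return ImagingVolume(grid=grid, channels=channels)


def make_scene(
    grid: VoxelGrid,
    n_branches: int = 2,
    target_length: float = 100.0,
    density: float = 0.19,
    coloc_fraction: float = 0.74,
    optics: OpticsNoiseModel = OpticsNoiseModel(),
    params: RenderParams | None = None,
    seed: int = 0,
    jitter_um: float = 0.1,
    n_exact: int | None = None,
    render: bool = True,
) -> GroundTruthScene:
    """Convenience wrapper: filaments -> puncta -> (optionally) rendered volume.

    Sub-seeds for the three stochastic stages are derived from ``seed`` so a
    single integer reproduces the whole scene.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    s_fil, s_pun, s_opt = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    fil = generate_filaments(grid, n_branches, target_length, seed=s_fil)
    pun = place_puncta(
        fil, density, coloc_fraction, seed=s_pun, jitter_um=jitter_um, grid=grid,
        n_exact=n_exact,
    )
    vol = None
    if render:
        vol = render_scene(grid, fil, pun, replace(optics, seed=s_opt), params)
    return GroundTruthScene(
        grid=grid,
        filaments=fil,
        puncta=pun,
        volume=vol,
        jitter_um=jitter_um,
        meta={"seed": seed, "density": density, "coloc_fraction": coloc_fraction},
    )


def write_ground_truth(scene: GroundTruthScene, path) -> None:
    """Write the scene's punctum manifest as CSV (see :mod:`glomquant.io`)."""
    from .io import write_manifest

    write_manifest(scene.puncta, path)
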