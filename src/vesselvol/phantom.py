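"""Ground-truthed synthetic angiographic phantoms.

Emulates contrast-cast vessels as seen in micro-CT of radiopaque
silicone-perfused specimens or contrast-filled clinical CTA: bright tubes
on a dark background, softened by partial-volume blur, with additive
Gaussian reconstruction-like noise. Every phantom carries an analytic
truth object (axis curves, radius profiles, quadrature volumes, expected
topology) so each imaging stage can be validated without scan data.

Rasterization computes per-voxel occupancy by k^3 supersampling of the
tube indicator (a sample is inside iff its distance to the axis is at most
the local radius), scales it between background and foreground intensity,
then applies Gaussian blur (physical sigma) and seeded Gaussian noise.
Occupancy is exact up to supersampling, and the same spec with the same
seed always reproduces the identical grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.integrate import quad
from scipy.spatial import cKDTree

from .errors import DataError
from .grid import UL_PER_CUBIC_UNIT, VoxelGrid

# -- axis curves ------------------------------------------------------------


@dataclass
class Line:
    p0: tuple
    p1: tuple

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, float)
        self.p1 = np.asarray(self.p1, float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def closed(self) -> bool:
        return False

    def point(self, s):
        t = np.atleast_1d(np.asarray(s, float) / self.length)
        return self.p0 + t[:, None] * (self.p1 - self.p0)


@dataclass
class Arc:
    """Circular arc of given radius in the plane normal to `normal`;
    a full 2*pi span makes a closed ring."""

    center: tuple
    normal: tuple
    radius: float
    angle_start: float = 0.0
    angle_end: float = 2 * np.pi

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        n = np.asarray(self.normal, float)
        self.normal = n / np.linalg.norm(n)
        if self.radius <= 0:
            raise DataError("arc radius must be > 0")
        # orthonormal in-plane basis, deterministic
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        self._u = np.cross(self.normal, ref)
        self._u /= np.linalg.norm(self._u)
        self._v = np.cross(self.normal, self._u)

    @property
    def length(self) -> float:
        return self.radius * abs(self.angle_end - self.angle_start)

    @property
    def closed(self) -> bool:
        return abs(abs(self.angle_end - self.angle_start) - 2 * np.pi) < 1e-9

    def point(self, s):
        ang = self.angle_start + np.atleast_1d(np.asarray(s, float)) / self.radius * np.sign(
            self.angle_end - self.angle_start
        )
        return (
            self.center
            + self.radius * np.cos(ang)[:, None] * self._u
            + self.radius * np.sin(ang)[:, None] * self._v
        )


@dataclass
class Polyline:
    control_points: np.ndarray

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, float)
        seg = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        self._s = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self._s[-1])

    @property
    def closed(self) -> bool:
        return bool(np.allclose(self.control_points[0], self.control_points[-1]))

    def point(self, s):
        s = np.atleast_1d(np.asarray(s, float))
        return np.stack(
            [np.interp(s, self._s, self.control_points[:, i]) for i in range(3)], axis=1
        )


# -- radius profiles --------------------------------------------------------


@dataclass
class ConstantRadius:
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise DataError("radius must be > 0")

    def __call__(self, s):
        return np.full_like(np.atleast_1d(np.asarray(s, float)), self.radius)


@dataclass
class FocalStenosis:
    """Constant baseline radius with a focal reduction by `fraction`
    (plateau of full reduction of width `width` centered at `center`,
    cosine tapers of length `taper` on both sides)."""

    radius: float
    fraction: float
    center: float
    width: float
    taper: float

    def __post_init__(self):
        if self.radius <= 0:
            raise DataError("radius must be > 0")
        if not 0 <= self.fraction < 1:
            raise DataError("stenosis fraction must satisfy 0 <= f < 1")
        if self.width < 0 or self.taper < 0:
            raise DataError("width and taper must be >= 0")

    def __call__(self, s):
        d = np.abs(np.atleast_1d(np.asarray(s, float)) - self.center)
        g = np.zeros_like(d)
        g[d <= self.width / 2] = 1.0
        if self.taper > 0:
            ramp = (d > self.width / 2) & (d <= self.width / 2 + self.taper)
            g[ramp] = 0.5 * (1 + np.cos(np.pi * (d[ramp] - self.width / 2) / self.taper))
        return self.radius * (1 - self.fraction * g)

    @property
    def plateau(self) -> tuple[float, float]:
        """Arc-length interval of full radius reduction."""
        return (self.center - self.width / 2, self.center + self.width / 2)


@dataclass
class Tube:
    curve: object
    profile: object


# -- spec & truth -----------------------------------------------------------


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    tubes: list[Tube]
    unit: str = "um"
    foreground: float = 255.0
    background: float = 0.0
    blur_sigma: float = 0.0  # physical units
    noise_sigma: float = 0.0  # intensity units
    seed: int | None = None
    supersample: int = 3

    def __post_init__(self):
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise DataError("blur and noise sigma must be >= 0")
        if self.noise_sigma > 0 and self.seed is None:
            raise DataError("a seed is mandatory when noise_sigma > 0")
        if self.supersample < 1:
            raise DataError("supersample factor must be >= 1")


@dataclass
class PhantomTruth:
    """Analytic description of the generated tubes."""

    tubes: list[Tube]
    unit: str
    n_endpoints: int | None = None
    n_branches: int | None = None
    n_cycles: int | None = None
    extras: dict = field(default_factory=dict)

    def radius(self, tube_index: int, s):
        return self.tubes[tube_index].profile(s)

    def axis_point(self, tube_index: int, s) -> np.ndarray:
        return self.tubes[tube_index].curve.point(s)[0]

    def tube_volume(self, tube_index: int, s0: float | None = None, s1: float | None = None) -> float:
        """Analytic volume of one tube (or a sub-interval) via quadrature of
        pi * r(s)^2 ds, in cubic `unit`."""
        tube = self.tubes[tube_index]
        s0 = 0.0 if s0 is None else s0
        s1 = tube.curve.length if s1 is None else s1
        val, _ = quad(lambda s: np.pi * float(tube.profile(s)[0]) ** 2, s0, s1, limit=400)
        return float(val)

    def tube_volume_ul(self, tube_index: int, s0=None, s1=None) -> float:
        return self.tube_volume(tube_index, s0, s1) * UL_PER_CUBIC_UNIT[self.unit]

    @property
    def total_volume(self) -> float:
        return float(sum(self.tube_volume(i) for i in range(len(self.tubes))))

    @property
    def total_volume_ul(self) -> float:
        return self.total_volume * UL_PER_CUBIC_UNIT[self.unit]


# -- rasterization ----------------------------------------------------------


def rasterize(spec: PhantomSpec, truth: PhantomTruth | None = None) -> tuple[VoxelGrid, PhantomTruth]:
    """Render a phantom spec to a voxel grid with its analytic truth."""
    spacing = np.asarray(spec.spacing, float)
    shape = np.asarray(spec.shape, int)
    _check_margins(spec, spacing, shape)

    occupancy = np.zeros(tuple(shape), dtype=np.float64)
    diag = float(np.linalg.norm(spacing))
    k = spec.supersample
    frac = (np.arange(k) + 0.5) / k - 0.5
    offsets = np.stack(np.meshgrid(frac, frac, frac, indexing="ij"), axis=-1).reshape(-1, 3)
    offsets = offsets * spacing  # physical supersample offsets within a voxel

    for tube in spec.tubes:
        ds = float(min(spacing)) / 4.0
        n = max(int(np.ceil(tube.curve.length / ds)) + 1, 2)
        s = np.linspace(0.0, tube.curve.length, n)
        centers = tube.curve.point(s)
        radii = np.asarray(tube.profile(s), float)
        tree = cKDTree(centers)
        rmax = float(radii.max())
        # open tubes end in flat caps normal to the tangent, so the solid
        # volume equals the quadrature of pi r(s)^2 ds exactly
        capped = not tube.curve.closed
        t_out0 = centers[0] - centers[1]
        t_out0 /= np.linalg.norm(t_out0)
        t_out1 = centers[-1] - centers[-2]
        t_out1 /= np.linalg.norm(t_out1)

        lo = np.maximum(np.floor((centers.min(axis=0) - rmax) / spacing).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((centers.max(axis=0) + rmax) / spacing).astype(int) + 2, shape)
        grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
        vox_idx = np.stack([g.ravel() for g in grids], axis=1)
        vox_pos = vox_idx * spacing

        def _inside(pts, d, i):
            ok = d <= radii[i]
            if capped:
                for end, t_out in ((0, t_out0), (n - 1, t_out1)):
                    at_end = i == end
                    if at_end.any():
                        proj = (pts[at_end] - centers[end]) @ t_out
                        ok[at_end] &= proj <= ds / 2
            return ok

        d1, i1 = tree.query(vox_pos, k=1)
        near = d1 <= radii[i1] + diag
        full = d1 <= radii[i1] - diag
        if capped:  # end regions always need supersampling
            full &= np.linalg.norm(vox_pos - centers[0], axis=1) > rmax + diag
            full &= np.linalg.norm(vox_pos - centers[-1], axis=1) > rmax + diag
        occ = np.zeros(len(vox_idx))
        occ[full] = 1.0
        boundary = near & ~full
        if boundary.any():
            pts = (vox_pos[boundary][:, None, :] + offsets[None, :, :]).reshape(-1, 3)
            dq, iq = tree.query(pts, k=min(4, n))
            inside = np.zeros(len(pts), dtype=bool)
            for col in range(dq.shape[1] if dq.ndim > 1 else 1):
                d_c = dq[:, col] if dq.ndim > 1 else dq
                i_c = iq[:, col] if iq.ndim > 1 else iq
                inside |= _inside(pts, d_c, i_c)
            occ[boundary] = inside.reshape(-1, len(offsets)).mean(axis=1)
        sel = occ > 0
        ii = vox_idx[sel]
        np.maximum.at(occupancy, (ii[:, 0], ii[:, 1], ii[:, 2]), occ[sel])

    intensity = spec.background + (spec.foreground - spec.background) * occupancy
    if spec.blur_sigma > 0:
        intensity = ndi.gaussian_filter(intensity, sigma=spec.blur_sigma / spacing)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=intensity.shape)

    grid = VoxelGrid(data=intensity, spacing=tuple(spacing), unit=spec.unit)
    if truth is None:
        truth = PhantomTruth(tubes=spec.tubes, unit=spec.unit)
    return grid, truth


def _check_margins(spec: PhantomSpec, spacing, shape) -> None:
    margin_lo = 2 * spacing
    margin_hi = (shape - 3) * spacing
    for tube in spec.tubes:
        s = np.linspace(0.0, tube.curve.length, 512)
        pts = tube.curve.point(s)
        r = np.asarray(tube.profile(s), float)[:, None]
        if np.any(pts - r < margin_lo - 1e-9) or np.any(pts + r > margin_hi + 1e-9):
            raise DataError(
                "phantom curve (with its radius) escapes the grid; keep a >= 2-voxel margin"
            )


# -- presets ----------------------------------------------------------------


def preset_tube(
    radius_voxels: float = 4.0,
    length_voxels: float = 60.0,
    spacing: float = 15.0,
    unit: str = "um",
    blur_sigma_voxels: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    supersample: int = 3,
) -> tuple[VoxelGrid, PhantomTruth]:
    """Straight axis-aligned tube (along x), centered in y/z."""
    r = radius_voxels * spacing
    length = length_voxels * spacing
    # odd lateral extent: the axis sits on integer voxel centers, which
    # keeps iterative thinning well-behaved on perfectly symmetric tubes
    lateral = 2 * int(np.ceil(radius_voxels)) + 9
    nx = int(np.ceil(length_voxels + 2 * radius_voxels + 8))
    cy = (lateral - 1) / 2 * spacing
    x0 = (radius_voxels + 3) * spacing
    tube = Tube(Line((x0, cy, cy), (x0 + length, cy, cy)), ConstantRadius(r))
    spec = PhantomSpec(
        shape=(nx, lateral, lateral),
        spacing=(spacing,) * 3,
        tubes=[tube],
        unit=unit,
        blur_sigma=blur_sigma_voxels * spacing,
        noise_sigma=noise_sigma,
        seed=seed,
        supersample=supersample,
    )
    truth = PhantomTruth([tube], unit, n_endpoints=2, n_branches=0, n_cycles=0)
    return rasterize(spec, truth)


def preset_stenosis(
    radius_voxels: float = 5.5,
    length_voxels: float = 120.0,
    severity: float = 0.2,
    spacing: float = 15.0,
    unit: str = "um",
    blur_sigma_voxels: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    supersample: int = 3,
) -> tuple[VoxelGrid, PhantomTruth]:
    """Straight tube with a focal stenosis at mid-length."""
    r = radius_voxels * spacing
    length = length_voxels * spacing
    lateral = 2 * int(np.ceil(radius_voxels)) + 9
    nx = int(np.ceil(length_voxels + 2 * radius_voxels + 8))
    cy = (lateral - 1) / 2 * spacing
    x0 = (radius_voxels + 3) * spacing
    profile = FocalStenosis(
        radius=r, fraction=severity, center=length / 2, width=length / 6, taper=length / 12
    )
    tube = Tube(Line((x0, cy, cy), (x0 + length, cy, cy)), profile)
    spec = PhantomSpec(
        shape=(nx, lateral, lateral),
        spacing=(spacing,) * 3,
        tubes=[tube],
        unit=unit,
        blur_sigma=blur_sigma_voxels * spacing,
        noise_sigma=noise_sigma,
        seed=seed,
        supersample=supersample,
    )
    truth = PhantomTruth(
        [tube], unit, n_endpoints=2, n_branches=0, n_cycles=0,
        extras={"stenosis_plateau": profile.plateau, "severity": severity},
    )
    return rasterize(spec, truth)


def preset_bifurcation(
    radius_voxels: float = 3.0,
    spacing: float = 15.0,
    unit: str = "um",
    blur_sigma_voxels: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    supersample: int = 3,
) -> tuple[VoxelGrid, PhantomTruth]:
    """Y-shaped bifurcation: a stem splitting into two oblique branches."""
    r = radius_voxels * spacing
    sp = spacing
    shape = (64, 64, 25)
    cz = 12 * sp
    junction = np.array([30 * sp, 31 * sp, cz])
    stem = Tube(Line((8 * sp, 31 * sp, cz), junction), ConstantRadius(r))
    b1 = Tube(Line(junction, (54 * sp, 52 * sp, cz)), ConstantRadius(r))
    b2 = Tube(Line(junction, (54 * sp, 11 * sp, cz)), ConstantRadius(r))
    spec = PhantomSpec(
        shape=shape, spacing=(sp,) * 3, tubes=[stem, b1, b2], unit=unit,
        blur_sigma=blur_sigma_voxels * sp, noise_sigma=noise_sigma, seed=seed,
        supersample=supersample,
    )
    truth = PhantomTruth(
        [stem, b1, b2], unit, n_endpoints=3, n_branches=1, n_cycles=0,
        extras={"junction": junction},
    )
    return rasterize(spec, truth)


def preset_ring(
    ring_radius_voxels: float = 20.0,
    tube_radius_voxels: float = 3.0,
    spacing: float = 15.0,
    unit: str = "um",
    blur_sigma_voxels: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    supersample: int = 3,
) -> tuple[VoxelGrid, PhantomTruth]:
    """Closed circular vessel (torus), e.g. an idealized circle of Willis loop."""
    sp = spacing
    R = ring_radius_voxels * sp
    r = tube_radius_voxels * sp
    lateral = 2 * int(np.ceil(ring_radius_voxels + tube_radius_voxels)) + 11
    nz = 2 * int(np.ceil(tube_radius_voxels)) + 9
    c = (lateral - 1) / 2 * sp
    cz = (nz - 1) / 2 * sp
    ring = Tube(Arc((c, c, cz), (0, 0, 1), R), ConstantRadius(r))
    spec = PhantomSpec(
        shape=(lateral, lateral, nz), spacing=(sp,) * 3, tubes=[ring], unit=unit,
        blur_sigma=blur_sigma_voxels * sp, noise_sigma=noise_sigma, seed=seed,
        supersample=supersample,
    )
    truth = PhantomTruth(
        [ring], unit, n_endpoints=0, n_branches=0, n_cycles=1,
        extras={"circumference": 2 * np.pi * R},
    )
    return rasterize(spec, truth)


@dataclass
class VasospasmPair:
    """Matched sham/spastic phantom pair with shared geometry."""

    sham_grid: VoxelGrid
    sham_truth: PhantomTruth
    sah_grid: VoxelGrid
    sah_truth: PhantomTruth
    severity: float
    anchor_s: float
    stenosis_plateau: tuple[float, float]

    @property
    def expected_diameter_ratio(self) -> float:
        return 1.0 - self.severity

    @property
    def expected_volume_ratio(self) -> float:
        return (1.0 - self.severity) ** 2


def preset_vasospasm_pair(
    severity: float = 0.2,
    seed: int = 0,
    radius: float = 82.5,
    spacing: float = 15.0,
    noise_sigma: float = 8.0,
    blur_sigma_voxels: float = 0.5,
    supersample: int = 3,
) -> VasospasmPair:
    """Matched pair of tubes emulating a sham vessel and one with focal
    vasospasm (default 20% radius reduction, the magnitude reported for
    proximal cerebral arteries a few days after experimental hemorrhage).

    Geometry mirrors the murine micro-CT setting: 15 um isotropic voxels,
    baseline radius 82.5 um (sham MCA scale, diameter 165 um), a 3.5 mm
    axis with the spasm plateau of 0.5 mm centered 2.3 mm from the
    proximal end. The diameter ratio at the plateau center is (1 - f) and
    the plateau volume ratio (1 - f)^2 by construction.
    """
    if not 0 <= severity < 1:
        raise DataError("severity must satisfy 0 <= f < 1")
    sp = spacing
    shape = (250, 33, 33)
    cy = 16 * sp
    x0, length = 115.0 * (sp / 15.0), 3500.0 * (sp / 15.0)
    line = Line((x0, cy, cy), (x0 + length, cy, cy))
    sham_profile = ConstantRadius(radius)
    sah_profile = FocalStenosis(
        radius=radius, fraction=severity, center=2300.0 * (sp / 15.0),
        width=500.0 * (sp / 15.0), taper=250.0 * (sp / 15.0),
    )

    def _make(profile, sub_seed):
        tube = Tube(line, profile)
        spec = PhantomSpec(
            shape=shape, spacing=(sp,) * 3, tubes=[tube], unit="um",
            blur_sigma=blur_sigma_voxels * sp, noise_sigma=noise_sigma,
            seed=sub_seed if noise_sigma > 0 else None, supersample=supersample,
        )
        truth = PhantomTruth([tube], "um", n_endpoints=2, n_branches=0, n_cycles=0)
        return rasterize(spec, truth)

    # same seed for both members: identical noise realization on matched
    # geometry, so severity 0 yields a bitwise-identical pair
    sham_grid, sham_truth = _make(sham_profile, seed)
    sah_grid, sah_truth = _make(sah_profile, seed)
    sah_truth.extras.update({"stenosis_plateau": sah_profile.plateau, "severity": severity})
    return VasospasmPair(
        sham_grid, sham_truth, sah_grid, sah_truth,
        severity=severity,
        anchor_s=1000.0 * (sp / 15.0),
        stenosis_plateau=sah_profile.plateau,
    )
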