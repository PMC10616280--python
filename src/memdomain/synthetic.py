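"""Synthetic-data generators with known ground truth.

Everything the analysis stages consume can be generated here under a fixed
seed: autocorrelation curves obeying 1- or 2-population 2D lateral diffusion,
z-scan diffusion-time grids following the Gaussian-beam waist profile,
Brownian trajectory ensembles, and voxelized confocal-like z-stacks of a
fluorescent spherical shell carrying signal-free membrane domains (geodesic
caps or stripes) with PSF blur and Poisson noise.

Conventions: lag times in s, diffusion times in ms, lengths in um,
diffusion coefficients in um^2/s.  Noise models are multiplicative Gaussian
(coefficient-of-variation) on G and on tau_d — the analysis consumes curves,
not photon streams, so photon-level simulation is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .fcs import ACFCurve, ZScanSeries, acf_model

__all__ = [
    "ACFModelParams",
    "OpticsSpec",
    "SyntheticTruth",
    "GUVImageSpec",
    "TrajectoryEnsemble",
    "ImageStack",
    "default_lag_grid",
    "fibonacci_sphere",
    "gen_acf_curve",
    "gen_diffusion_time_grid",
    "gen_brownian_trajectories",
    "gen_guv_stack",
    "spherical_cap_area",
    "spherical_stripe_area",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class ACFModelParams:
    """Ground-truth parameters of the 2D lateral diffusion ACF model."""

    n_particles: float                 # mean occupancy N of the focal spot
    tau_d: Sequence[float]             # 1-2 diffusion times, ms, ascending
    fractions: Sequence[float] = (1.0,)
    offset: float = 0.0

    def __post_init__(self):
        self.tau_d = tuple(float(t) for t in self.tau_d)
        self.fractions = tuple(float(f) for f in self.fractions)
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if not 1 <= len(self.tau_d) <= 2 or len(self.tau_d) != len(self.fractions):
            raise ValueError("need 1-2 populations with matching fractions")
        if any(t <= 0 for t in self.tau_d):
            raise ValueError("tau_d must be strictly positive")
        if len(self.tau_d) == 2 and not self.tau_d[0] < self.tau_d[1]:
            raise ValueError("two-population tau_d must be ascending")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class OpticsSpec:
    """Beam geometry of one spot-variation measurement series.

    The effective waist grows away from the focus following the Gaussian-beam
    relation omega(z)^2 = omega0^2 (1 + (lambda z / (pi n omega0^2))^2).
    """

    waist_w0: float                    # um, waist at focus
    wavelength: float = 488.0          # nm (488 nm excitation)
    refractive_index: float = 1.333
    z_offsets: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0)  # um

    def __post_init__(self):
        self.z_offsets = tuple(float(z) for z in self.z_offsets)
        if self.waist_w0 <= 0 or self.wavelength <= 0 or self.refractive_index <= 0:
            raise ValueError("optics parameters must be positive")
        if len(self.z_offsets) < 5:
            raise ValueError("need >=5 z offsets per vesicle")
        if not any(abs(z) < 1e-12 for z in self.z_offsets):
            raise ValueError("z offsets must include 0 (the focus)")

    def waist_sq(self, z) -> np.ndarray:
        """omega(z)^2 in um^2 for axial offset z in um."""
        lam_um = self.wavelength * 1e-3
        w0sq = self.waist_w0**2
        zr = np.pi * self.refractive_index * w0sq / lam_um  # Rayleigh range, um
        return w0sq * (1.0 + (np.asarray(z, dtype=float) / zr) ** 2)


@dataclass
class SyntheticTruth:
    """Ground-truth diffusion law: D_eff (um^2/s), t0 (ms), confinement kind."""

    d_eff: float
    t0: float = 0.0
    kind: str = "free"

    def __post_init__(self):
        if self.d_eff <= 0:
            raise ValueError("d_eff must be positive")
        if self.kind not in ("free", "domain", "meshwork"):
            raise ValueError("kind must be free|domain|meshwork")
        if self.kind == "free" and abs(self.t0) > 1e-12:
            raise ValueError("free diffusion implies t0 = 0")


@dataclass
class TrajectoryEnsemble:
    """Ensemble of 2D Brownian trajectories with known diffusion coefficient."""

    positions: np.ndarray              # (n_particles, n_steps, 2), um
    dt: float                          # s
    d_true: float                      # um^2/s

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n, steps, 2)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class ImageStack:
    """A voxel z-stack with calibration (ZYX axis order, um units)."""

    data: np.ndarray                   # (nz, ny, nx)
    voxel_size: Tuple[float, float, float]   # (dz, dy, dx) um
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # center of voxel [0,0,0]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3D (ZYX)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass
class GUVImageSpec:
    """Recipe for a synthetic GUV z-stack with planted signal-free domains.

    ``domain_plan`` entries are (shape, angular_size, position): for a "cap"
    the angular size is the half-angle of the geodesic disk about the given
    direction; for a "stripe" it is the full angular width of a band centred
    on the great circle perpendicular to the given axis.
    """

    radius: float                      # um
    voxel_size: Tuple[float, float, float] = (0.2, 0.2, 0.2)
    center: Tuple[float, float, float] = None   # um; default: stack centre
    shell_sigma: float = 0.2           # um, PSF-like blur of the shell
    domain_plan: List[tuple] = field(default_factory=list)
    photon_scale: float = 100.0        # expected photons at shell peak
    poisson_noise: bool = True
    pad: float = 2.0                   # um of empty margin around the vesicle
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.shell_sigma <= 0 or self.photon_scale <= 0:
            raise ValueError("radius, shell_sigma, photon_scale must be positive")
        for shape, ang, pos in self.domain_plan:
            if shape not in ("cap", "stripe"):
                raise ValueError(f"unknown domain shape {shape!r}")
            if not 0 < ang < np.pi:
                raise ValueError("domain angular sizes must lie in (0, pi)")


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def default_lag_grid(n: int = 150, lo: float = 1e-6, hi: float = 1.0) -> np.ndarray:
    """Logarithmic lag grid in seconds (typical hardware-correlator layout)."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def gen_acf_curve(params: ACFModelParams, lags=None, noise_scale: float = 0.0,
                  seed: int = 0, **meta) -> ACFCurve:
    """Evaluate the ACF model on a lag grid and add multiplicative noise.

    The perturbation is zero-mean Gaussian with s.d. ``noise_scale * G(tau)``
    per point, emulating the shot-noise-like scatter of measured curves.
    """
    if lags is None:
        lags = default_lag_grid()
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag grid")
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    g = acf_model(lags, params.n_particles, params.tau_d, params.fractions,
                  params.offset)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + noise_scale * rng.standard_normal(g.shape))
    return ACFCurve(lags=lags, g=g, **meta)


def gen_diffusion_time_grid(truth: SyntheticTruth, optics: Sequence[OpticsSpec],
                            n_vesicles: int = 5, noise_cv: float = 0.0,
                            seed: int = 0) -> List[ZScanSeries]:
    """Diffusion-time grids tau_d(z) for every waist and vesicle.

    tau_d(z) = [omega(z)^2 / (4 D_eff) + t0] * (1 + eps), eps ~ N(0, noise_cv),
    with omega(z) following the Gaussian-beam profile of each OpticsSpec.
    """
    if n_vesicles < 1:
        raise ValueError("n_vesicles must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    w0_min = min(o.waist_w0 for o in optics)
    tau_focus = w0_min**2 / (4.0 * truth.d_eff) * 1e3 + truth.t0
    if tau_focus <= 0:
        raise ValueError(
            f"t0={truth.t0} ms gives nonpositive tau_d at the smallest waist")

    rng = np.random.default_rng(seed)
    series: List[ZScanSeries] = []
    for opt in optics:
        z = np.asarray(opt.z_offsets, dtype=float)
        base = opt.waist_sq(z) / (4.0 * truth.d_eff) * 1e3 + truth.t0  # ms
        for v in range(n_vesicles):
            eps = noise_cv * rng.standard_normal(z.shape) if noise_cv > 0 else 0.0
            series.append(ZScanSeries(
                z=z, tau_d=base * (1.0 + eps), waist=opt.waist_w0,
                vesicle_id=f"w{opt.waist_w0:g}_v{v}"))
    return series


def gen_brownian_trajectories(d_true: float, n: int, steps: int, dt: float,
                              seed: int = 0) -> TrajectoryEnsemble:
    """Free 2D Brownian motion: per-axis increments ~ N(0, 2 D dt)."""
    if n < 1 or steps < 2:
        raise ValueError("need n >= 1 particles and steps >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if d_true < 0:
        raise ValueError("d_true must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * d_true * dt)
    inc = sigma * rng.standard_normal((n, steps - 1, 2))
    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(inc, axis=1)], axis=1)
    return TrajectoryEnsemble(positions=pos, dt=dt, d_true=d_true)


# --------------------------------------------------------------------------
# GUV image stacks
# --------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-angle lattice)."""
    i = np.arange(n)
    golden = (1.0 + 5.0**0.5) / 2.0
    theta = 2.0 * np.pi * i / golden
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def spherical_cap_area(radius: float, half_angle: float) -> float:
    """Area of a geodesic cap of the given half-angle, 2 pi R^2 (1 - cos theta)."""
    return 2.0 * np.pi * radius**2 * (1.0 - np.cos(half_angle))


def spherical_stripe_area(radius: float, width_angle: float) -> float:
    """Area of a band of full angular width centred on a great circle."""
    return 4.0 * np.pi * radius**2 * np.sin(width_angle / 2.0)


def _domain_mask(directions: np.ndarray, plan) -> np.ndarray:
    """Boolean mask of unit vectors falling inside any planted domain."""
    inside = np.zeros(directions.shape[0], dtype=bool)
    for shape, ang, pos in plan:
        axis = np.asarray(pos, dtype=float)
        axis = axis / np.linalg.norm(axis)
        cosang = directions @ axis
        if shape == "cap":
            inside |= cosang >= np.cos(ang)
        else:  # stripe: band around the great circle perpendicular to axis
            inside |= np.abs(cosang) <= np.sin(ang / 2.0)
    return inside


def gen_guv_stack(spec: GUVImageSpec):
    """Voxelize a fluorescent spherical shell with signal-free domains.

    Intensity = photon_scale * exp(-(r - R)^2 / (2 sigma^2)) masked to zero
    where the surface direction falls inside a planted domain, then Poisson
    sampled (unless ``poisson_noise`` is off).  Returns the stack and the
    analytic ground truth as a ``DomainSet`` (areas from spherical geometry).
    """
    from .domains import Domain, DomainSet

    r_total = spec.radius + spec.pad
    dz, dy, dx = spec.voxel_size
    nz = int(np.ceil(2 * r_total / dz))
    ny = int(np.ceil(2 * r_total / dy))
    nx = int(np.ceil(2 * r_total / dx))
    if spec.center is None:
        center = np.array([nz * dz / 2, ny * dy / 2, nx * dx / 2])
    else:
        center = np.asarray(spec.center, dtype=float)
        lo = center - spec.radius
        hi = center + spec.radius
        if np.any(lo < 0) or np.any(hi > [nz * dz, ny * dy, nx * dx]):
            raise ValueError("vesicle does not fit inside the stack")

    zc = (np.arange(nz) + 0.5) * dz - center[0]
    yc = (np.arange(ny) + 0.5) * dy - center[1]
    xc = (np.arange(nx) + 0.5) * dx - center[2]
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    r = np.sqrt(Z * Z + Y * Y + X * X)
    shell = np.exp(-((r - spec.radius) ** 2) / (2.0 * spec.shell_sigma**2))

    if spec.domain_plan:
        with np.errstate(invalid="ignore"):
            dirs = np.stack([Z, Y, X], axis=-1) / np.maximum(r, 1e-12)[..., None]
        # direction components ordered (z, y, x); domain positions use (x, y, z)
        dirs_xyz = dirs[..., ::-1].reshape(-1, 3)
        inside = _domain_mask(dirs_xyz, spec.domain_plan).reshape(r.shape)
        if np.all(_domain_mask(fibonacci_sphere(2000), spec.domain_plan)):
            raise ValueError("domain plan covers the whole sphere: no signal left")
        shell = np.where(inside, 0.0, shell)

    lam = spec.photon_scale * shell
    if spec.poisson_noise:
        rng = np.random.default_rng(spec.seed)
        data = rng.poisson(lam).astype(np.uint16)
    else:
        data = lam
    stack = ImageStack(data=data, voxel_size=spec.voxel_size,
                       origin=(0.0, 0.0, 0.0))

    R = spec.radius
    truth_domains = []
    for shape, ang, pos in spec.domain_plan:
        axis = np.asarray(pos, dtype=float)
        axis = axis / np.linalg.norm(axis)
        if shape == "cap":
            area = spherical_cap_area(R, ang)
            boundary = 2.0 * np.pi * R * np.sin(ang)
            extent = 2.0 * R * ang      # geodesic diameter
        else:
            area = spherical_stripe_area(R, ang)
            lat = np.pi / 2.0 - ang / 2.0
            boundary = 2.0 * 2.0 * np.pi * R * np.sin(lat)
            extent = np.pi * R          # wraps around the sphere
        truth_domains.append(Domain(
            members=None, area=area, boundary_length=boundary,
            centroid=axis * R, max_extent=extent, label=shape))
    truth = DomainSet(domains=truth_domains, source="image",
                      total_surface_area=4.0 * np.pi * R**2, radius=R)
    return stack, truth
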