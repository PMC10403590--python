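"""Monte Carlo photon transport for illumination design.

Vectorized photon-packet random walk in a homogeneous scattering slab:
exponential step sampling with µt = µa + µs, Henyey–Greenstein scattering,
absorption-weight deposition at each interaction, and Russian-roulette
termination.  Used to compare the three candidate illumination geometries of
the wearable probe — a grid of micro-lens focal spots, a clear centre
window, and oblique side illumination — via the deposited-fluence
distribution and the −20 dB effective-illumination-area metric.

Refractive-index mismatches at the surface are not modelled (photons that
exit the slab are counted as escaped); the index field is carried for
bookkeeping only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, MeasurementError, UsageError

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 0.1


@dataclass
class OpticalMedium:
    """Homogeneous optical properties: µa, µs in cm⁻¹ (converted to mm⁻¹
    internally), Henyey–Greenstein anisotropy g, refractive index n."""

    mua: float  # cm^-1
    mus: float  # cm^-1
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise UsageError("absorption/scattering coefficients must be >= 0")
        if not (-1.0 < self.g < 1.0):
            raise UsageError("anisotropy must lie in (−1, 1)")

    @property
    def mua_mm(self) -> float:
        return self.mua / 10.0

    @property
    def mus_mm(self) -> float:
        return self.mus / 10.0

    @property
    def mut_mm(self) -> float:
        return (self.mua + self.mus) / 10.0


def dermis_532() -> OpticalMedium:
    """Dermis at 532 nm: µs = 357 cm⁻¹, µa = 0.46 cm⁻¹ (g, n assumed)."""
    return OpticalMedium(mua=0.46, mus=357.0, g=0.9, n=1.4)


@dataclass
class IlluminationGeometry:
    """kind: lens_grid | center_window | side.

    ``footprint`` is the half-side (mm) of the square device aperture the
    light must cover.  lens_grid: ``n_spots``² converging beamlets of entry
    radius ``spot_radius`` focused ``focal_depth`` below the surface on a grid
    of pitch ``pitch`` (default footprint·2/n_spots).  center_window: uniform
    collimated square window of half-side ``window_half``.  side: photons
    enter from the four footprint edges tilted inward by ``incidence_deg``.
    """

    kind: str
    footprint: float = 4.98
    n_spots: int = 5
    pitch: float | None = None
    spot_radius: float = 0.2
    focal_depth: float = 0.5
    window_half: float = 2.0
    incidence_deg: float = 45.0

    def __post_init__(self):
        if self.kind not in ("lens_grid", "center_window", "side"):
            raise UsageError(f"unknown illumination kind '{self.kind}'")
        if self.pitch is None:
            self.pitch = 2.0 * self.footprint / self.n_spots
        for v in (self.footprint, self.pitch, self.spot_radius, self.window_half):
            if v <= 0:
                raise UsageError("geometry parameters must be positive")


@dataclass
class FluenceMap:
    """Deposited-energy map (a.u.) on a voxel grid with bookkeeping totals."""

    values: np.ndarray  # (nx, ny, nz)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    n_photons: int
    seed: int
    deposited: float = 0.0
    escaped: float = 0.0
    extra: dict = field(default_factory=dict)

    def depth_slice(self, depth: float) -> np.ndarray:
        iz = int(round((depth - self.origin[2]) / self.spacing[2]))
        iz = np.clip(iz, 0, self.values.shape[2] - 1)
        return self.values[:, :, iz]

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing[i] * np.arange(self.values.shape[i])


def _launch(geom: IlluminationGeometry, n: int, rng: np.random.Generator):
    """Initial positions (n,3) and unit directions (n,3) at the z=0 surface."""
    if geom.kind == "lens_grid":
        k = geom.n_spots
        offs = (np.arange(k) - (k - 1) / 2.0) * geom.pitch
        cx, cy = np.meshgrid(offs, offs, indexing="ij")
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        which = rng.integers(0, len(centers), n)
        r = geom.spot_radius * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        px = centers[which, 0] + r * np.cos(th)
        py = centers[which, 1] + r * np.sin(th)
        pos = np.column_stack([px, py, np.zeros(n)])
        # converging beamlet: aim at the focal point below the spot centre
        tgt = np.column_stack(
            [centers[which, 0], centers[which, 1], np.full(n, geom.focal_depth)]
        )
        d = tgt - pos
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return pos, d
    if geom.kind == "center_window":
        px = geom.window_half * (2 * rng.random(n) - 1)
        py = geom.window_half * (2 * rng.random(n) - 1)
        pos = np.column_stack([px, py, np.zeros(n)])
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        return pos, d
    # side illumination: entry along the four edges, tilted toward the centre
    edge = rng.integers(0, 4, n)
    along = geom.footprint * (2 * rng.random(n) - 1)
    f = geom.footprint
    px = np.where(edge == 0, -f, np.where(edge == 1, f, along))
    py = np.where(edge == 2, -f, np.where(edge == 3, f, along))
    pos = np.column_stack([px, py, np.zeros(n)])
    ang = np.deg2rad(geom.incidence_deg)
    # horizontal component points inward (toward the footprint centre axis)
    hdir = np.zeros((n, 2))
    hdir[edge == 0, 0] = 1.0
    hdir[edge == 1, 0] = -1.0
    hdir[edge == 2, 1] = 1.0
    hdir[edge == 3, 1] = -1.0
    d = np.column_stack(
        [np.sin(ang) * hdir[:, 0], np.sin(ang) * hdir[:, 1], np.full(n, np.cos(ang))]
    )
    return pos, d


def _hg_scatter(d: np.ndarray, g: float, rng: np.random.Generator) -> np.ndarray:
    """Henyey–Greenstein deflection of unit direction vectors."""
    n = len(d)
    u = rng.random(n)
    if abs(g) < 1e-6:
        cos_t = 2 * u - 1
    else:
        tmp = (1 - g * g) / (1 - g + 2 * g * u)
        cos_t = (1 + g * g - tmp * tmp) / (2 * g)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1 - cos_t**2)
    phi = 2 * np.pi * rng.random(n)
    cp, sp = np.cos(phi), np.sin(phi)

    dz = d[:, 2]
    near_pole = np.abs(dz) > 0.99999
    denom = np.sqrt(np.maximum(1 - dz**2, 1e-24))
    nx = (sin_t * (d[:, 0] * dz * cp - d[:, 1] * sp)) / denom + d[:, 0] * cos_t
    ny = (sin_t * (d[:, 1] * dz * cp + d[:, 0] * sp)) / denom + d[:, 1] * cos_t
    nz = -sin_t * cp * denom + dz * cos_t
    out = np.column_stack([nx, ny, nz])
    # polar special case: scatter relative to ±z
    pole = np.column_stack([sin_t * cp, sin_t * sp, np.sign(dz) * cos_t])
    out[near_pole] = pole[near_pole]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def mc_fluence(
    geom: IlluminationGeometry,
    medium: OpticalMedium,
    n_photons: int,
    seed: int,
    grid_half: float = 6.0,
    z_max: float = 3.0,
    spacing_xy: float = 0.1,
    spacing_z: float = 0.1,
    max_events: int = 10_000,
) -> FluenceMap:
    """Run the photon random walk and accumulate deposited weight per voxel.

    Deterministic for a fixed seed.  Photons leaving the slab (z < 0 or
    z > z_max) or wandering far outside the lateral grid are tallied as
    escaped; total deposited + escaped equals the launched weight up to the
    roulette's unbiased variance.
    """
    if medium.mut_mm <= 0:
        raise ConfigurationError("µt = 0 in an unbounded medium never interacts")
    if n_photons < 10_000:
        warnings.warn("fewer than 1e4 photons: fluence maps will be noisy",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    nx = ny = int(round(2 * grid_half / spacing_xy))
    nz = int(round(z_max / spacing_z))
    vol = np.zeros(nx * ny * nz)
    origin = (-grid_half, -grid_half, 0.0)

    pos, dirn = _launch(geom, n_photons, rng)
    w = np.ones(n_photons)
    albedo = medium.mus_mm / medium.mut_mm
    mut = medium.mut_mm
    deposited = 0.0
    escaped = 0.0
    lateral_cut = grid_half * 3.0

    for _ in range(max_events):
        if len(w) == 0:
            break
        step = -np.log(rng.random(len(w))) / mut
        pos = pos + dirn * step[:, None]

        gone = (
            (pos[:, 2] < 0)
            | (pos[:, 2] >= z_max)
            | (np.abs(pos[:, 0]) > lateral_cut)
            | (np.abs(pos[:, 1]) > lateral_cut)
        )
        escaped += float(w[gone].sum())
        keep = ~gone
        pos, dirn, w = pos[keep], dirn[keep], w[keep]
        if len(w) == 0:
            break

        dep = w * (1.0 - albedo)
        ix = ((pos[:, 0] - origin[0]) / spacing_xy).astype(np.int64)
        iy = ((pos[:, 1] - origin[1]) / spacing_xy).astype(np.int64)
        iz = (pos[:, 2] / spacing_z).astype(np.int64)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        flat = (ix[inside] * ny + iy[inside]) * nz + iz[inside]
        np.add.at(vol, flat, dep[inside])
        deposited += float(dep.sum())
        w = w * albedo

        low = w < _ROULETTE_THRESHOLD
        if np.any(low):
            survive = rng.random(low.sum()) < _ROULETTE_SURVIVAL
            kill = low.copy()
            kill[np.where(low)[0][survive]] = False
            w = np.where(low, w / _ROULETTE_SURVIVAL, w)
            keep = ~kill
            pos, dirn, w = pos[keep], dirn[keep], w[keep]
            if len(w) == 0:
                break

        dirn = _hg_scatter(dirn, medium.g, rng)

    return FluenceMap(
        values=vol.reshape(nx, ny, nz) / n_photons,
        spacing=(spacing_xy, spacing_xy, spacing_z),
        origin=origin,
        n_photons=n_photons,
        seed=seed,
        deposited=deposited / n_photons,
        escaped=escaped / n_photons,
    )


def effective_area_fraction(
    fmap: FluenceMap,
    depth: float,
    threshold_db: float = -20.0,
    roi_half: float | None = None,
    smooth_sigma: float = 1.0,
) -> float:
    """Fraction of the footprint at ``depth`` within ``threshold_db`` of the
    slice maximum; its complement is the blind region.

    The dB drop is taken on intensity (factor 10 in the exponent).  The slice
    is lightly Gaussian-smoothed (σ in voxels) before thresholding to keep
    the estimate stable against Monte Carlo shot noise; ``roi_half`` defaults
    to the device footprint stored on the map or the full grid.
    """
    sl = fmap.depth_slice(depth).astype(float)
    if smooth_sigma > 0:
        sl = gaussian_filter(sl, smooth_sigma)
    x = fmap.axis(0)
    y = fmap.axis(1)
    if roi_half is not None:
        mx = np.abs(x) <= roi_half
        my = np.abs(y) <= roi_half
        sl = sl[np.ix_(mx, my)]
    peak = sl.max()
    if peak <= 0:
        raise MeasurementError("all-zero fluence slice")
    thr = peak * 10.0 ** (threshold_db / 10.0)
    return float(np.mean(sl >= thr))
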