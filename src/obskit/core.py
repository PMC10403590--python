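"""Core domain types for optoacoustic channel data, media, and volumes.

Conventions used throughout the toolkit: right-handed coordinates with z
positive into tissue and the (planar) sensor array at z = 0; lengths in mm,
times in µs, frequencies in MHz.  Sound speeds are accepted in m/s (the unit
used in the literature) and converted to mm/µs internally where needed
(1500 m/s = 1.5 mm/µs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, UsageError, ValidationError

MM_PER_US_PER_M_PER_S = 1e-3  # 1 m/s = 1e-3 mm/µs


def mps_to_mmus(c_m_per_s: float) -> float:
    """Convert a sound speed from m/s to mm/µs."""
    return c_m_per_s * MM_PER_US_PER_M_PER_S


@dataclass
class SensorArray:
    """A planar (or registered near-planar) grid of rectangular receive elements.

    Parameters
    ----------
    element_centers : (n, 3) array
        Element centre positions in mm.  For a regular grid the centres are
        ordered row-major (x fastest).
    nx, ny : int
        Grid shape; ``nx * ny`` must equal the number of elements.
    element_width, element_height : float
        Element aperture sides in mm.
    gap : float
        Inter-element gap in mm (pitch = width + gap along x).
    center_frequency : float
        Nominal centre frequency in MHz.
    fractional_bandwidth : float
        −6 dB fractional bandwidth (1.0 means 100%).
    sampling_rate : float
        Temporal sampling rate in MHz.
    out_of_plane : (n,) array, optional
        Per-element out-of-plane displacement Δz (mm) from geometry
        registration; zero for a perfectly planar array.
    """

    element_centers: np.ndarray
    nx: int
    ny: int
    element_width: float
    element_height: float
    gap: float
    center_frequency: float
    fractional_bandwidth: float
    sampling_rate: float
    out_of_plane: np.ndarray | None = None

    def __post_init__(self):
        self.element_centers = np.asarray(self.element_centers, dtype=float)
        if self.element_centers.ndim != 2 or self.element_centers.shape[1] != 3:
            raise GeometryError("element_centers must be an (n, 3) array")
        n = self.element_centers.shape[0]
        if n < 1:
            raise GeometryError("array must contain at least one element")
        if self.nx * self.ny != n:
            raise GeometryError(
                f"grid {self.nx}x{self.ny} inconsistent with {n} elements"
            )
        if self.gap < 0:
            raise ValidationError("gap must be non-negative")
        if self.fractional_bandwidth < 0:
            raise ValidationError("fractional bandwidth must be >= 0")
        f_top = self.center_frequency * (1.0 + self.fractional_bandwidth / 2.0)
        if self.sampling_rate <= 2.0 * f_top:
            raise ValidationError(
                f"sampling rate {self.sampling_rate} MHz violates Nyquist for "
                f"band edge {f_top} MHz"
            )
        if self.out_of_plane is None:
            self.out_of_plane = np.zeros(n)
        else:
            self.out_of_plane = np.asarray(self.out_of_plane, dtype=float)
            if self.out_of_plane.shape != (n,):
                raise GeometryError("out_of_plane must have one entry per element")

    @property
    def n_elements(self) -> int:
        return self.element_centers.shape[0]

    @property
    def pitch_x(self) -> float:
        return self.element_width + self.gap

    @property
    def pitch_y(self) -> float:
        return self.element_height + self.gap

    @property
    def is_planar(self) -> bool:
        return bool(np.allclose(self.out_of_plane, 0.0))

    @classmethod
    def regular_grid(
        cls,
        nx: int,
        ny: int,
        element_width: float,
        gap: float,
        center_frequency: float,
        fractional_bandwidth: float,
        sampling_rate: float,
        element_height: float | None = None,
    ) -> "SensorArray":
        """Build a centred planar nx × ny grid at z = 0."""
        if element_height is None:
            element_height = element_width
        px = element_width + gap
        py = element_height + gap
        xs = (np.arange(nx) - (nx - 1) / 2.0) * px
        ys = (np.arange(ny) - (ny - 1) / 2.0) * py
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        centers = np.column_stack(
            [gx.ravel(), gy.ravel(), np.zeros(nx * ny)]
        )
        return cls(
            element_centers=centers,
            nx=nx,
            ny=ny,
            element_width=element_width,
            element_height=element_height,
            gap=gap,
            center_frequency=center_frequency,
            fractional_bandwidth=fractional_bandwidth,
            sampling_rate=sampling_rate,
        )


def device_array(sampling_rate: float = 50.0) -> SensorArray:
    """The 6×6 stethoscope receive grid: 2.28 mm² elements, 0.15 mm gaps,
    7.8 MHz centre frequency, 100% fractional bandwidth."""
    side = float(np.sqrt(2.28))
    return SensorArray.regular_grid(
        nx=6, ny=6, element_width=side, gap=0.15,
        center_frequency=7.8, fractional_bandwidth=1.0,
        sampling_rate=sampling_rate,
    )


@dataclass
class LayeredMedium:
    """Ordered acoustic layers below the array plane.

    ``layers`` is a list of (thickness mm, sound speed m/s); the last layer may
    be half-infinite (thickness ``np.inf``).
    """

    layers: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValidationError("medium needs at least one layer")
        self.layers = [(float(d), float(c)) for d, c in self.layers]
        for i, (d, c) in enumerate(self.layers):
            last = i == len(self.layers) - 1
            if not last and not (0 < d < np.inf):
                raise ValidationError("inner layer thicknesses must be finite and > 0")
            if last and d <= 0:
                raise ValidationError("layer thickness must be > 0")
            if c <= 0:
                raise ValidationError("sound speeds must be > 0")

    @property
    def L(self) -> int:
        return len(self.layers)

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([d for d, _ in self.layers])

    @property
    def speeds_mps(self) -> np.ndarray:
        return np.array([c for _, c in self.layers])

    @property
    def speeds_mmus(self) -> np.ndarray:
        return self.speeds_mps * MM_PER_US_PER_M_PER_S

    def interface_depths(self) -> np.ndarray:
        """Depths of the layer tops: z_1 = 0, z_{l+1} = z_l + d_l."""
        d = self.thicknesses[:-1]
        return np.concatenate([[0.0], np.cumsum(d)])

    def layer_of_depth(self, z: float) -> int:
        """Index of the layer containing depth z (>= 0)."""
        if z < 0:
            raise UsageError("depth must be non-negative")
        tops = self.interface_depths()
        return int(np.searchsorted(tops, z, side="right") - 1)

    def total_thickness(self) -> float:
        return float(np.sum(self.thicknesses))


@dataclass
class ChannelData:
    """Received pressure p(x, y, z=0, t) on the element grid.

    ``samples`` is real-valued, indexed (element_x, element_y, time);
    ``t0``/``dt`` are in µs.
    """

    samples: np.ndarray
    t0: float
    dt: float
    geometry: SensorArray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValidationError("samples must be (nx, ny, nt)")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")
        nx, ny, _ = self.samples.shape
        if (nx, ny) != (self.geometry.nx, self.geometry.ny):
            raise GeometryError(
                f"samples grid {nx}x{ny} does not match declared geometry "
                f"{self.geometry.nx}x{self.geometry.ny}"
            )

    @property
    def n_times(self) -> int:
        return self.samples.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_times)


@dataclass
class ReconGrid:
    """Voxel lattice for reconstruction: counts and physical extents (mm)."""

    nx: int
    ny: int
    nz: int
    x_extent: tuple[float, float]
    y_extent: tuple[float, float]
    z_extent: tuple[float, float]

    def __post_init__(self):
        for n in (self.nx, self.ny, self.nz):
            if n < 2:
                raise ValidationError("voxel counts must be >= 2")
        for lo, hi in (self.x_extent, self.y_extent, self.z_extent):
            if hi <= lo:
                raise ValidationError("extents must be increasing intervals")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (
            (self.x_extent[1] - self.x_extent[0]) / (self.nx - 1),
            (self.y_extent[1] - self.y_extent[0]) / (self.ny - 1),
            (self.z_extent[1] - self.z_extent[0]) / (self.nz - 1),
        )

    @property
    def x(self) -> np.ndarray:
        return np.linspace(*self.x_extent, self.nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(*self.y_extent, self.ny)

    @property
    def z(self) -> np.ndarray:
        return np.linspace(*self.z_extent, self.nz)


@dataclass
class TrendSeries:
    """Time-stamped peak-to-peak ROI amplitudes (the input to all
    physiological fits).  Timestamps in s, strictly increasing; ``roi`` is a
    free label, conventionally one of {vein, artery, tissue}."""

    timestamps: np.ndarray
    values: np.ndarray
    roi: str = "vein"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise ValidationError("timestamps and values must be matching 1D arrays")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trend values must be finite")


@dataclass
class ReconVolume:
    """Reconstructed source amplitude S(x, y, z) on a voxel grid."""

    voxels: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    layer_boundaries: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if np.iscomplexobj(self.voxels):
            raise ValidationError("volume must be real-valued")
        self.voxels = self.voxels.astype(float)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxels must be finite")

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing[i] * np.arange(self.voxels.shape[i])

    def peak_position(self) -> tuple[float, float, float]:
        """Position (mm) of the voxel of maximum |S|."""
        idx = np.unravel_index(np.argmax(np.abs(self.voxels)), self.voxels.shape)
        return tuple(self.origin[i] + self.spacing[i] * idx[i] for i in range(3))
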