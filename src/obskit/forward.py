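"""Optoacoustic forward model and physiological protocol generator.

The channel simulator is the toolkit's independent ground-truth oracle: every
absorber is treated as a point source radiating a band-limited pulse that
arrives at each (point-like) receive element after the refracted, layered
travel time, with 1/r geometric spreading.  It deliberately shares no code
with the reconstruction path beyond the Fermat travel-time solver that both
are tested against a brute-force scan.

The protocol generator emulates the amplitude time courses of the in-vivo
experiments: hypoxia cycling (230 s cycles = 50 s low + 180 s normal oxygen,
with a venous lag), venous/arterial cuff occlusion steps (+23% / −37%), and
exogenous-agent washout (default decay coefficient 3.6e-4 s⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ChannelData, LayeredMedium, ReconGrid, SensorArray, TrendSeries
from .errors import UsageError, ValidationError
from .raypaths import times_at_depth

_TWO_SQRT_2LN2 = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PulseModel:
    """Band-limited optoacoustic pulse surrogate.

    ``n_shape_bandlimited`` (default) is a Gaussian-windowed sinusoid whose
    envelope spectrum has the requested −6 dB fractional bandwidth — a
    band-limited stand-in for the bipolar N-shaped pressure pulse.
    ``gaussian_derivative`` is the first derivative of a Gaussian with its
    spectral peak at the centre frequency (bandwidth fixed by the shape).
    """

    center_frequency: float  # MHz
    fractional_bandwidth: float = 1.0
    shape: str = "n_shape_bandlimited"

    def __post_init__(self):
        if self.fractional_bandwidth <= 0:
            raise ValidationError("bandwidth must be > 0")
        if self.shape not in ("n_shape_bandlimited", "gaussian_derivative"):
            raise ValidationError(f"unknown pulse shape '{self.shape}'")

    @property
    def sigma_t(self) -> float:
        """Envelope standard deviation in µs."""
        if self.shape == "gaussian_derivative":
            return 1.0 / (2.0 * np.pi * self.center_frequency)
        sigma_f = self.fractional_bandwidth * self.center_frequency / _TWO_SQRT_2LN2
        return 1.0 / (2.0 * np.pi * sigma_f)

    @property
    def half_support(self) -> float:
        """Effective half-duration (µs) beyond which the pulse is negligible."""
        return 5.0 * self.sigma_t

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the pulse at times ``t`` (µs, centred on arrival)."""
        t = np.asarray(t, dtype=float)
        s = self.sigma_t
        if self.shape == "gaussian_derivative":
            # normalized so the extrema have unit magnitude
            return -(t / s) * np.exp(0.5 - t * t / (2.0 * s * s))
        return np.sin(2.0 * np.pi * self.center_frequency * t) * np.exp(
            -t * t / (2.0 * s * s)
        )


@dataclass
class Phantom:
    """Collection of point absorbers and tubular vessels inside a volume.

    ``point_sources``: list of ((x, y, z) mm, amplitude); ``vessels``: list of
    (polyline (n, 3) mm, radius mm, amplitude).  ``bounds`` is the declared
    enclosing box ((x0, x1), (y0, y1), (z0, z1)).
    """

    point_sources: list = field(default_factory=list)
    vessels: list = field(default_factory=list)
    bounds: tuple = ((-10.0, 10.0), (-10.0, 10.0), (0.0, 20.0))

    def __post_init__(self):
        for pos, amp in self.point_sources:
            self._check_inside(np.asarray(pos, dtype=float))
            if amp < 0:
                raise ValidationError("amplitudes must be >= 0")
        for polyline, radius, amp in self.vessels:
            pl = np.asarray(polyline, dtype=float)
            if pl.ndim != 2 or pl.shape[1] != 3 or pl.shape[0] < 2:
                raise ValidationError("vessel polyline must be (n>=2, 3)")
            for p in pl:
                self._check_inside(p)
            if radius <= 0 or amp < 0:
                raise ValidationError("vessel radius must be > 0 and amplitude >= 0")

    def _check_inside(self, p: np.ndarray):
        for i, (lo, hi) in enumerate(self.bounds):
            if not (lo <= p[i] <= hi):
                raise ValidationError(
                    f"phantom geometry at {tuple(p)} outside declared volume"
                )

    def as_point_sources(self, spacing: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
        """All sources as (positions (n, 3), amplitudes (n,)).

        Vessels are sampled as point absorbers on an axis-aligned lattice of
        pitch ``spacing`` restricted to the tube interior, each carrying
        amplitude × lattice-cell volume so the total source strength matches
        the tube's analytic volume as the lattice refines.
        """
        pts, amps = [], []
        for pos, amp in self.point_sources:
            pts.append(np.asarray(pos, dtype=float))
            amps.append(float(amp))
        for polyline, radius, amp in self.vessels:
            centers = _tube_lattice(np.asarray(polyline, float), radius, spacing)
            cell = spacing**3
            for c in centers:
                pts.append(c)
                amps.append(amp * cell)
        if not pts:
            return np.zeros((0, 3)), np.zeros(0)
        return np.vstack(pts), np.asarray(amps)

    def rasterize(self, grid: ReconGrid) -> np.ndarray:
        """Ground-truth amplitude volume on a reconstruction grid."""
        out = np.zeros((grid.nx, grid.ny, grid.nz))
        x, y, z = grid.x, grid.y, grid.z
        for pos, amp in self.point_sources:
            ix = np.argmin(np.abs(x - pos[0]))
            iy = np.argmin(np.abs(y - pos[1]))
            iz = np.argmin(np.abs(z - pos[2]))
            out[ix, iy, iz] += amp
        if self.vessels:
            gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            for polyline, radius, amp in self.vessels:
                d = _dist_to_polyline(pts, np.asarray(polyline, float))
                out.ravel()[d <= radius] = amp
        return out


def _dist_to_polyline(pts: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (segment-wise projection)."""
    best = np.full(len(pts), np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab)
        d = np.linalg.norm(pts - proj, axis=1)
        best = np.minimum(best, d)
    return best


def _tube_lattice(polyline: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    lo = polyline.min(axis=0) - radius
    hi = polyline.max(axis=0) + radius
    axes = [np.arange(lo[i], hi[i] + spacing, spacing) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = _dist_to_polyline(pts, polyline)
    return pts[d <= radius]


def make_phantom(spec: dict) -> Phantom:
    """Build a phantom from a declarative description.

    Keys: ``bounds`` (optional), ``points``: list of {position, amplitude},
    ``vessels``: list of {polyline, radius, amplitude}.
    """
    bounds = tuple(tuple(b) for b in spec.get(
        "bounds", ((-10.0, 10.0), (-10.0, 10.0), (0.0, 20.0))
    ))
    points = [
        (tuple(p["position"]), float(p.get("amplitude", 1.0)))
        for p in spec.get("points", [])
    ]
    vessels = [
        (np.asarray(v["polyline"], dtype=float), float(v["radius"]),
         float(v.get("amplitude", 1.0)))
        for v in spec.get("vessels", [])
    ]
    return Phantom(point_sources=points, vessels=vessels, bounds=bounds)


def simulate_channels(
    phantom: Phantom,
    array: SensorArray,
    medium: LayeredMedium,
    pulse: PulseModel,
    t0: float = 0.0,
    n_times: int | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    vessel_spacing: float = 0.15,
    element_subdivision: int = 1,
) -> ChannelData:
    """Simulate band-limited channel data for a phantom (forward oracle).

    Each point absorber contributes ``a / r · pulse(t − τ)`` at every element,
    where τ is the refracted (Fermat) travel time through the layered medium
    and r the Euclidean source–element distance.  Additive white Gaussian
    noise of standard deviation ``noise_sd`` is applied with the given seed.

    By default elements are point receivers (the oracle assumption that keeps
    this model independent of the receive-field module).  With
    ``element_subdivision`` = s > 1 each element face is sampled on an s × s
    sub-grid and the responses averaged, which reproduces the finite-aperture
    directivity of large elements (the device's 1.5 mm faces are strongly
    directive at 7.8 MHz).
    """
    positions, amplitudes = phantom.as_point_sources(vessel_spacing)
    if np.any(positions[:, 2] < 0):
        raise ValidationError("sources must lie at z >= 0 (below the array plane)")
    depth_limit = medium.total_thickness()
    if np.isfinite(depth_limit) and np.any(positions[:, 2] > depth_limit):
        raise ValidationError("sources must lie inside the layered medium")

    dt = 1.0 / array.sampling_rate
    if n_times is None:
        # cover the farthest arrival plus the pulse tail
        if len(positions):
            zmax = positions[:, 2].max()
            rho_max = 0.0
            for e in array.element_centers:
                d = np.hypot(positions[:, 0] - e[0], positions[:, 1] - e[1]).max()
                rho_max = max(rho_max, float(d))
            tmax = float(
                times_at_depth(np.array([rho_max]), zmax, medium, "refracted")[0]
            )
        else:
            tmax = 1.0
        n_times = int(np.ceil((tmax + 2 * pulse.half_support - t0) / dt)) + 8

    nx, ny = array.nx, array.ny
    samples = np.zeros((nx * ny, n_times))
    s = max(int(element_subdivision), 1)
    if s > 1:
        offs = (np.arange(s) + 0.5) / s - 0.5
        ox, oy = np.meshgrid(offs * array.element_width,
                             offs * array.element_height, indexing="ij")
        ox, oy = ox.ravel(), oy.ravel()
        ex = (array.element_centers[:, 0][:, None] + ox[None, :]).ravel()
        ey = (array.element_centers[:, 1][:, None] + oy[None, :]).ravel()
        elem_idx = np.repeat(np.arange(nx * ny), s * s)
        sub_weight = 1.0 / (s * s)
    else:
        ex = array.element_centers[:, 0]
        ey = array.element_centers[:, 1]
        elem_idx = np.arange(nx * ny)
        sub_weight = 1.0
    half = pulse.half_support
    wlen = int(np.ceil(2 * half / dt)) + 2

    # group sources by depth so the layered solver runs once per depth value
    if len(positions):
        order = np.argsort(positions[:, 2], kind="stable")
        positions = positions[order]
        amplitudes = amplitudes[order]
        zs = positions[:, 2]
        start = 0
        while start < len(zs):
            stop = start
            while stop < len(zs) and zs[stop] == zs[start]:
                stop += 1
            block = slice(start, stop)
            z = float(zs[start])
            dxs = positions[block, 0][:, None] - ex[None, :]
            dys = positions[block, 1][:, None] - ey[None, :]
            rho = np.hypot(dxs, dys)
            tau = times_at_depth(rho, z, medium, "refracted")
            r = np.sqrt(rho**2 + z**2)
            r = np.maximum(r, 1e-3)
            gains = sub_weight * amplitudes[block][:, None] / r
            i0 = np.floor((tau - half - t0) / dt).astype(int)
            win = np.arange(wlen)
            for si in range(tau.shape[0]):
                idx = i0[si][:, None] + win[None, :]
                valid = (idx >= 0) & (idx < n_times)
                tt = t0 + idx * dt - tau[si][:, None]
                vals = gains[si][:, None] * pulse.waveform(tt)
                flat = (elem_idx[:, None] * n_times + idx)[valid]
                np.add.at(samples.ravel(), flat, vals[valid])
            start = stop

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, samples.shape)
    samples = samples.reshape(nx, ny, n_times)
    return ChannelData(samples=samples, t0=t0, dt=dt, geometry=array)


@dataclass
class ProtocolSpec:
    """Physiological amplitude protocol for the trend generator.

    kinds
    -----
    hypoxia_cycle
        Square-wave cycling: ``low_duration`` s of low oxygen then
        ``cycle_duration − low_duration`` s of normal oxygen per cycle;
        amplitude drops by ``delta_pct`` during the low phase.  Venous ROIs
        lag the arterial response by ``venous_delay`` s.
    occlusion_vein / occlusion_artery
        Step change of ``delta_pct`` while the cuff is inflated
        (between ``t_on`` and ``t_off``).
    agent_decay
        Exponential washout ``baseline·[(1−m)·e^(−k t) + m]`` with decay
        coefficient ``decay_rate`` (s⁻¹) and static background fraction
        ``mixing_fraction`` m (the non-clearing part of the ROI signal).
    """

    kind: str
    baseline: float = 100.0
    delta_pct: float | None = None
    cycle_duration: float = 230.0
    low_duration: float = 50.0
    t_on: float = 60.0
    t_off: float = 160.0
    venous_delay: float = 10.0
    decay_rate: float = 3.6e-4
    mixing_fraction: float = 0.0
    noise_sd: float = 0.0

    _DEFAULT_DELTAS = {
        "hypoxia_cycle": -38.0,
        "occlusion_vein": +23.0,
        "occlusion_artery": -37.0,
        "agent_decay": 0.0,
    }

    def __post_init__(self):
        if self.kind not in self._DEFAULT_DELTAS:
            raise UsageError(f"unknown protocol kind '{self.kind}'")
        if self.delta_pct is None:
            self.delta_pct = self._DEFAULT_DELTAS[self.kind]
        if self.delta_pct <= -100.0:
            raise ValidationError("amplitude delta must exceed −100%")
        for d in (self.cycle_duration, self.low_duration):
            if d <= 0:
                raise ValidationError("durations must be positive")
        if self.low_duration >= self.cycle_duration:
            raise ValidationError("low phase must be shorter than the cycle")


def simulate_trend_series(
    protocol: ProtocolSpec,
    duration: float,
    dt: float,
    seed: int | None = None,
    roi: str = "artery",
) -> TrendSeries:
    """Generate a protocol-shaped amplitude trend with seeded noise."""
    if not (duration > dt > 0):
        raise ValidationError("need duration > dt > 0")
    t = np.arange(0.0, duration, dt)
    base = protocol.baseline
    delta = base * protocol.delta_pct / 100.0
    if protocol.kind == "hypoxia_cycle":
        lag = protocol.venous_delay if roi == "vein" else 0.0
        phase = np.mod(t - lag, protocol.cycle_duration)
        low = phase < protocol.low_duration
        values = base + delta * low
    elif protocol.kind in ("occlusion_vein", "occlusion_artery"):
        occluded = (t >= protocol.t_on) & (t < protocol.t_off)
        values = base + delta * occluded
    else:  # agent_decay
        m = protocol.mixing_fraction
        values = base * ((1.0 - m) * np.exp(-protocol.decay_rate * t) + m)
    if protocol.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, protocol.noise_sd, values.shape)
    return TrendSeries(timestamps=t, values=values, roi=roi)
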