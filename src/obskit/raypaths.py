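"""Travel times through horizontally layered media.

Two ray models are provided:

``straight``
    Integrate slowness along the straight segment between element and voxel
    (per-layer path lengths over per-layer speeds).  This is the classical
    approximation that ignores refraction at layer interfaces.

``refracted``
    Fermat's least-time path honouring Snell's law at every interface.  The
    minimization is solved with the ray-parameter (horizontal slowness)
    formulation: for ray parameter p the horizontal offset
    X(p) = Σ_l Δz_l · p c_l / sqrt(1 − p²c_l²) increases monotonically, so the
    p matching a requested offset is found by bisection; the associated time
    is T(p) = Σ_l Δz_l / (c_l · sqrt(1 − p²c_l²)).  This is equivalent to the
    nested per-interface minimization but is exact and fast.
"""

from __future__ import annotations

import numpy as np

from .core import LayeredMedium
from .errors import ValidationError

_BISECT_ITERS = 64


def _path_segments(medium: LayeredMedium, z: float) -> tuple[np.ndarray, np.ndarray]:
    """Vertical extents (mm) and speeds (mm/µs) of the layers a ray to depth z crosses."""
    tops = medium.interface_depths()
    layer = medium.layer_of_depth(z)
    dz = []
    for l in range(layer):
        dz.append(medium.thicknesses[l])
    dz.append(z - tops[layer])
    c = medium.speeds_mmus[: layer + 1]
    return np.asarray(dz, dtype=float), np.asarray(c, dtype=float)


def _fermat_times(rho: np.ndarray, dz: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Refracted travel times (µs) for horizontal offsets ``rho`` (mm).

    ``dz``/``c`` are the per-layer vertical extents and speeds along the path.
    Vectorized bisection on the ray parameter.
    """
    rho = np.asarray(rho, dtype=float)
    pos = dz > 0
    dz = dz[pos]
    c = c[pos]
    if dz.size == 0:
        # horizontal path in the first layer
        return rho / c[0] if c.size else rho * np.nan
    if dz.size == 1:
        return np.hypot(rho, dz[0]) / c[0]
    p_hi = np.full(rho.shape, 1.0 / c.max())
    p_lo = np.zeros_like(rho)
    dzc = dz[:, None]
    cc = c[:, None]
    flat_rho = rho.ravel()
    lo = p_lo.ravel().copy()
    hi = p_hi.ravel().copy()
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        sin2 = (mid[None, :] * cc) ** 2
        sin2 = np.minimum(sin2, 1.0 - 1e-15)
        x = np.sum(dzc * mid[None, :] * cc / np.sqrt(1.0 - sin2), axis=0)
        too_far = x > flat_rho
        hi = np.where(too_far, mid, hi)
        lo = np.where(too_far, lo, mid)
    p = 0.5 * (lo + hi)
    sin2 = (p[None, :] * cc) ** 2
    sin2 = np.minimum(sin2, 1.0 - 1e-15)
    t = np.sum(dzc / (cc * np.sqrt(1.0 - sin2)), axis=0)
    return t.reshape(rho.shape)


def _straight_times(rho: np.ndarray, dz: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Straight-segment travel times (µs): slowness integrated along the chord."""
    rho = np.asarray(rho, dtype=float)
    z = float(np.sum(dz))
    if z == 0:
        return rho / c[0]
    path = np.hypot(rho, z)
    # each layer contributes in proportion to its vertical extent
    per_layer = path[..., None] * (dz / z)
    return np.sum(per_layer / c, axis=-1)


def times_at_depth(
    rho: np.ndarray, z: float, medium: LayeredMedium, ray_model: str = "refracted"
) -> np.ndarray:
    """Travel times (µs) from the z=0 plane to depth ``z`` at horizontal offsets ``rho``."""
    if z < 0:
        raise ValidationError("target depth must lie below the array plane")
    dz, c = _path_segments(medium, z)
    if ray_model == "refracted":
        return _fermat_times(np.asarray(rho, dtype=float), dz, c)
    if ray_model == "straight":
        return _straight_times(np.asarray(rho, dtype=float), dz, c)
    raise ValidationError(f"unknown ray model '{ray_model}'")


def travel_time(
    element_pos, voxel_pos, medium: LayeredMedium, ray_model: str = "refracted"
) -> float:
    """Travel time (µs) between an element on the z=0 plane and a voxel.

    The element's z coordinate must be 0 (pre-migration redatums bent arrays
    first); the voxel must lie at z >= 0.
    """
    e = np.asarray(element_pos, dtype=float)
    v = np.asarray(voxel_pos, dtype=float)
    if v[2] < 0:
        raise ValidationError("voxel lies above the array plane")
    rho = float(np.hypot(v[0] - e[0], v[1] - e[1]))
    return float(times_at_depth(np.array([rho]), float(v[2]), medium, ray_model)[0])


def travel_time_table(
    rho_grid: np.ndarray,
    z_grid: np.ndarray,
    medium: LayeredMedium,
    ray_model: str = "refracted",
) -> np.ndarray:
    """Table T[z_i, rho_j] of travel times (µs) for fast delay lookup."""
    out = np.empty((len(z_grid), len(rho_grid)))
    for i, z in enumerate(z_grid):
        out[i] = times_at_depth(rho_grid, float(z), medium, ray_model)
    return out


def fermat_scan_oracle(
    element_pos, voxel_pos, medium: LayeredMedium, n_scan: int = 10_000
) -> float:
    """Brute-force Fermat time for a two-layer medium by scanning the
    interface crossing point on a dense grid.  Independent check for
    :func:`travel_time`; only supports exactly two crossed layers."""
    e = np.asarray(element_pos, dtype=float)
    v = np.asarray(voxel_pos, dtype=float)
    rho = np.hypot(v[0] - e[0], v[1] - e[1])
    dz, c = _path_segments(medium, float(v[2]))
    if len(dz) != 2:
        raise ValidationError("scan oracle requires a path crossing two layers")
    x = np.linspace(0.0, rho, n_scan)
    t = np.hypot(x, dz[0]) / c[0] + np.hypot(rho - x, dz[1]) / c[1]
    return float(t.min())
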