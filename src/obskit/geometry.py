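"""Array-geometry registration from tracked skin-surface coordinates.

Before attaching the probe, a magnetically tracked pen records the skin
surface profile at the element sites.  Reconstruction assumes a planar
aperture, so the tracked point cloud is reduced to (i) a best-fit reference
plane and (ii) per-element out-of-plane displacements Δz that the
pre-migration step uses to redatum the traces.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def fit_reference_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through a 3D point cloud.

    Returns (centroid, unit normal).  Raises GeometryError for fewer than
    3 points or a (near-)collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("marker coordinates must be an (n, 3) array")
    if pts.shape[0] < 3:
        raise GeometryError("plane fitting needs at least 3 points")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    # singular vectors: smallest singular value -> normal direction
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    scale = s[0]
    if scale == 0 or s[1] / scale < 1e-10:
        raise GeometryError("marker points are collinear or coincident")
    normal = vt[2]
    if normal[2] < 0:  # orient normal toward +z for a stable sign convention
        normal = -normal
    return centroid, normal


def register_array_geometry(marker_coords: np.ndarray):
    """Register tracked element coordinates against a best-fit plane.

    Parameters
    ----------
    marker_coords : (n, 3) array
        Tracked positions of the element sites in mm (>= 3, non-collinear).

    Returns
    -------
    in_plane : (n, 3) array
        Element positions expressed in the plane's local frame (u, v, 0),
        i.e. the projections onto the reference plane.
    residuals : (n,) array
        Signed out-of-plane displacement Δz of each element (mm); all zero
        for coplanar input.  These feed ``psnufft.pre_migrate``.
    """
    pts = np.asarray(marker_coords, dtype=float)
    centroid, normal = fit_reference_plane(pts)
    q = pts - centroid
    residuals = q @ normal
    # local in-plane basis: two unit vectors orthogonal to the normal
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    in_plane = np.column_stack([q @ u, q @ v, np.zeros(len(pts))])
    return in_plane, residuals
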