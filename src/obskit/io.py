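"""File I/O: HDF5 channel containers, TIFF/NIfTI volume export, YAML configs.

Channel container layout (one HDF5 file):

    /channels            float64 (nx, ny, nt)   received pressure traces
    /geometry/centers    float64 (n, 3)         element centres (mm)
    /geometry/out_of_plane  float64 (n,)        registration residuals (mm)
    attrs: t0, dt (µs), fc (MHz), bw (fractional), fs (MHz),
           nx, ny, element_width, element_height, gap (mm)
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import ChannelData, LayeredMedium, ReconGrid, ReconVolume, SensorArray
from .errors import FormatError, GeometryError, UsageError

_REQUIRED_ATTRS = ("t0", "dt", "fc", "bw", "fs", "nx", "ny",
                   "element_width", "element_height", "gap")


def save_channel_data(data: ChannelData, path: str | Path) -> None:
    """Write a ChannelData record to an HDF5 container (lossless round trip)."""
    g = data.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("channels", data=data.samples)
        grp = f.create_group("geometry")
        grp.create_dataset("centers", data=g.element_centers)
        grp.create_dataset("out_of_plane", data=g.out_of_plane)
        f.attrs.update(
            t0=data.t0, dt=data.dt, fc=g.center_frequency,
            bw=g.fractional_bandwidth, fs=g.sampling_rate,
            nx=g.nx, ny=g.ny, element_width=g.element_width,
            element_height=g.element_height, gap=g.gap,
        )


def load_channel_data(path: str | Path) -> ChannelData:
    """Load a ChannelData record written by :func:`save_channel_data`.

    Raises
    ------
    FormatError
        If a required dataset or attribute is missing (named in the message).
    GeometryError
        If the trace grid does not match the declared element grid.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        for key in ("channels", "geometry/centers"):
            if key not in f:
                raise FormatError(f"container missing dataset '{key}'")
        for key in _REQUIRED_ATTRS:
            if key not in f.attrs:
                raise FormatError(f"container missing attribute '{key}'")
        samples = f["channels"][()]
        centers = f["geometry/centers"][()]
        oop = (
            f["geometry/out_of_plane"][()]
            if "geometry/out_of_plane" in f
            else None
        )
        a = dict(f.attrs)
    nx, ny = int(a["nx"]), int(a["ny"])
    if centers.shape[0] != nx * ny:
        raise GeometryError(
            f"{centers.shape[0]} traces inconsistent with declared "
            f"{nx}x{ny} grid"
        )
    geometry = SensorArray(
        element_centers=centers, nx=nx, ny=ny,
        element_width=float(a["element_width"]),
        element_height=float(a["element_height"]),
        gap=float(a["gap"]), center_frequency=float(a["fc"]),
        fractional_bandwidth=float(a["bw"]), sampling_rate=float(a["fs"]),
        out_of_plane=oop,
    )
    return ChannelData(samples=samples, t0=float(a["t0"]), dt=float(a["dt"]),
                       geometry=geometry)


def save_volume(volume: ReconVolume, path: str | Path, format: str = "tiff_stack") -> None:
    """Export a reconstructed volume as a TIFF z-stack or a NIfTI image.

    TIFF stacks hold one page per z slice with the voxel size recorded in the
    ImageJ-style resolution metadata; NIfTI encodes (dx, dy, dz) in the affine.
    """
    if volume.voxels.size == 0:
        raise UsageError("cannot export an empty volume")
    path = Path(path)
    dx, dy, dz = volume.spacing
    if format == "tiff_stack":
        import tifffile

        # pages indexed by z: transpose (x, y, z) -> (z, y, x)
        stack = np.ascontiguousarray(np.transpose(volume.voxels, (2, 1, 0)))
        tifffile.imwrite(
            path, stack.astype(np.float32), imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "mm", "axes": "ZYX"},
        )
    elif format == "nifti":
        import nibabel as nib

        affine = np.diag([dx, dy, dz, 1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    else:
        raise UsageError(f"unsupported volume format '{format}'")


def load_medium(path: str | Path) -> LayeredMedium:
    """Read a layered medium from a YAML file: list of {thickness_mm, speed_mps}."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    layers = [
        (float(l["thickness_mm"]), float(l["speed_mps"])) for l in cfg["layers"]
    ]
    return LayeredMedium(layers)


def load_array(path: str | Path) -> SensorArray:
    """Read a regular-grid sensor array description from YAML."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return SensorArray.regular_grid(
        nx=int(cfg["nx"]), ny=int(cfg["ny"]),
        element_width=float(cfg["element_width_mm"]),
        gap=float(cfg["gap_mm"]),
        center_frequency=float(cfg["center_frequency_mhz"]),
        fractional_bandwidth=float(cfg["fractional_bandwidth"]),
        sampling_rate=float(cfg["sampling_rate_mhz"]),
        element_height=(
            float(cfg["element_height_mm"]) if "element_height_mm" in cfg else None
        ),
    )


def load_grid(path_or_spec: str | Path) -> ReconGrid:
    """Read a reconstruction grid from YAML ({nx, ny, nz, x/y/z_extent_mm})."""
    with open(path_or_spec) as f:
        cfg = yaml.safe_load(f)
    return ReconGrid(
        nx=int(cfg["nx"]), ny=int(cfg["ny"]), nz=int(cfg["nz"]),
        x_extent=tuple(cfg["x_extent_mm"]),
        y_extent=tuple(cfg["y_extent_mm"]),
        z_extent=tuple(cfg["z_extent_mm"]),
    )
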