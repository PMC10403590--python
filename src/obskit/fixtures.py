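"""Packaged simulation fixtures for the reconstruction comparison studies.

``layered_phantom_study`` defines the toolkit's standard two-layer
resolution/contrast benchmark: a point absorber at x = 3.5 mm (depth 5 mm)
and a Y-shaped vessel, under a stiff dermis-like layer on soft tissue,
recorded by a dense planar aperture.  The Fourier-domain method is run with
the true layered model; the delay-and-sum arm is run the classical way — a
single assumed tissue speed and straight rays — which is precisely the
homogeneous-medium shortcut the layered method is designed to avoid.

``device_resolution_study`` characterizes the wearable 6×6 probe itself:
point targets at several depths, received with the finite 1.51 mm element
faces (whose directivity, not the aperture, limits the device's lateral
resolution), reconstructed in the time domain with refracted delays.

All fixture parameters are frozen here so tests and the acceptance script
operate on one documented configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LayeredMedium, ReconGrid, ReconVolume, SensorArray, device_array
from .das import DASConfig, reconstruct_das
from .forward import Phantom, PulseModel, simulate_channels
from .metrics import ROISpec, lateral_profile_through_peak, profile_fwhm
from .psnufft import NUFFTConfig, reconstruct

# --- layered phantom study (resolution + contrast comparison) --------------

POINT_SOURCE_POS = (3.5, 0.0, 5.0)
VESSEL_RADIUS = 0.4
DERMIS_THICKNESS = 3.0  # mm
DERMIS_SPEED = 1700.0  # m/s
TISSUE_SPEED = 1480.0  # m/s
CLASSICAL_DAS_SPEED = 1540.0  # the homogeneous-medium assumption, m/s
NOISE_FRACTION = 0.045  # channel noise sd relative to the peak channel amplitude


def layered_medium() -> LayeredMedium:
    """Stiff dermis-like layer over half-infinite soft tissue."""
    return LayeredMedium([(DERMIS_THICKNESS, DERMIS_SPEED), (np.inf, TISSUE_SPEED)])


def benchmark_array(nx: int = 40) -> SensorArray:
    """Dense planar aperture (0.25 mm pitch) for the simulation benchmark.

    The probe's own 1.66 mm pitch band-limits any Fourier reconstruction to
    roughly the pitch, so the simulation benchmark samples the same ~10 mm
    aperture densely — the regime the published comparison images are drawn
    from — while keeping the device's frequency response.
    """
    return SensorArray.regular_grid(
        nx=nx, ny=nx, element_width=0.2, gap=0.05,
        center_frequency=7.8, fractional_bandwidth=1.0, sampling_rate=50.0,
    )


def benchmark_phantom() -> Phantom:
    """Point absorber at x = 3.5 mm plus a Y-shaped vessel."""
    trunk = [(-3.8, -3.0, 5.4), (-2.0, -0.5, 5.0)]
    branch_a = [(-2.0, -0.5, 5.0), (-3.5, 2.5, 4.6)]
    branch_b = [(-2.0, -0.5, 5.0), (-0.5, 2.5, 4.8)]
    return Phantom(
        point_sources=[(POINT_SOURCE_POS, 1.0)],
        vessels=[
            (np.asarray(trunk), VESSEL_RADIUS, 1.0),
            (np.asarray(branch_a), VESSEL_RADIUS, 1.0),
            (np.asarray(branch_b), VESSEL_RADIUS, 1.0),
        ],
        bounds=((-6.0, 6.0), (-6.0, 6.0), (0.0, 12.0)),
    )


@dataclass
class ComparisonResult:
    psnufft: ReconVolume
    das: ReconVolume
    rois: ROISpec
    fwhm_psnufft: float
    fwhm_das: float
    cnr_psnufft: float
    cnr_das: float
    gcnr_psnufft: float
    gcnr_das: float


def _volume_rois(vol: ReconVolume, phantom: Phantom) -> ROISpec:
    """Signal ROI = the vessel interior; background = a clean slab above it."""
    xs, ys, zs = (vol.axis(0), vol.axis(1), vol.axis(2))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    from .forward import _dist_to_polyline

    sig = np.zeros(len(pts), dtype=bool)
    for polyline, radius, _ in phantom.vessels:
        sig |= _dist_to_polyline(pts, np.asarray(polyline)) <= radius
    # background: a slab well above every source, inside the aperture
    bg = (
        (np.abs(gx.ravel()) <= 4.0)
        & (np.abs(gy.ravel()) <= 4.0)
        & (gz.ravel() >= 3.2)
        & (gz.ravel() <= 3.9)
    )
    bg &= ~sig
    return ROISpec(
        signal=sig.reshape(vol.voxels.shape), background=bg.reshape(vol.voxels.shape)
    )


def run_comparison(
    seed: int = 0,
    grid_n: tuple[int, int, int] = (128, 128, 150),
    array_nx: int = 40,
) -> ComparisonResult:
    """Run the full benchmark: simulate once, reconstruct with both methods,
    measure −6 dB lateral FWHM through the point image, CNR, and gCNR on the
    shared fixture ROIs."""
    array = benchmark_array(array_nx)
    medium = layered_medium()
    phantom = benchmark_phantom()
    pulse = PulseModel(array.center_frequency, array.fractional_bandwidth)

    clean = simulate_channels(phantom, array, medium, pulse)
    noise_sd = NOISE_FRACTION * float(np.abs(clean.samples).max())
    rng = np.random.default_rng(seed)
    from .core import ChannelData

    data = ChannelData(
        samples=clean.samples + rng.normal(0.0, noise_sd, clean.samples.shape),
        t0=clean.t0, dt=clean.dt, geometry=array,
    )

    nx, ny, nz = grid_n
    grid = ReconGrid(
        nx=nx, ny=ny, nz=nz,
        x_extent=(-5.0, 5.0), y_extent=(-5.0, 5.0), z_extent=(3.0, 7.0),
    )
    vol_ps = reconstruct(data, medium, grid, NUFFTConfig(), envelope=True)

    # run DAS on the identical voxel lattice the Fourier method produced
    xs, ys = vol_ps.axis(0), vol_ps.axis(1)
    grid_das = ReconGrid(
        nx=vol_ps.voxels.shape[0], ny=vol_ps.voxels.shape[1], nz=nz,
        x_extent=(float(xs[0]), float(xs[-1])),
        y_extent=(float(ys[0]), float(ys[-1])),
        z_extent=(3.0, 7.0),
    )
    vol_das = reconstruct_das(
        data,
        LayeredMedium([(np.inf, CLASSICAL_DAS_SPEED)]),
        grid_das,
        DASConfig(ray_model="straight", envelope="abs_hilbert"),
    )

    rois = _volume_rois(vol_ps, phantom)
    from .metrics import cnr, gcnr

    def fwhm_of(vol):
        prof, coords = lateral_profile_through_peak(_point_region(vol), axis=0)
        return profile_fwhm(prof, coords)

    def _point_region(vol):
        # restrict the peak search to the point-source quadrant (x > 1)
        xs = vol.axis(0)
        sub = vol.voxels.copy()
        sub[xs < 1.0, :, :] = 0.0
        return ReconVolume(voxels=sub, origin=vol.origin, spacing=vol.spacing)

    return ComparisonResult(
        psnufft=vol_ps,
        das=vol_das,
        rois=rois,
        fwhm_psnufft=fwhm_of(vol_ps),
        fwhm_das=fwhm_of(vol_das),
        cnr_psnufft=cnr(vol_ps, rois),
        cnr_das=cnr(vol_das, rois),
        gcnr_psnufft=gcnr(vol_ps, rois),
        gcnr_das=gcnr(vol_das, rois),
    )


# --- device resolution study ----------------------------------------------

DEVICE_STUDY_DEPTHS = (2.0, 5.0, 10.0)


def device_resolution_study(
    depths=DEVICE_STUDY_DEPTHS, grid_nxy: int = 128, element_subdivision: int = 7
) -> list[float]:
    """−6 dB lateral FWHM (mm) of point targets imaged by the 6×6 probe.

    Channels include the finite element faces (directivity), and the image is
    formed in the time domain with refracted delays — emulating the physical
    point-target characterization of the device, whose lateral resolution is
    set by the 1.51 mm element aperture rather than the array width.
    """
    arr = device_array()
    med = LayeredMedium([(np.inf, 1500.0)])
    pulse = PulseModel(arr.center_frequency, arr.fractional_bandwidth)
    out = []
    for depth in depths:
        ph = Phantom(point_sources=[((0.8, 0.0, depth), 1.0)])
        cd = simulate_channels(
            ph, arr, med, pulse, element_subdivision=element_subdivision
        )
        grid = ReconGrid(
            nx=grid_nxy, ny=grid_nxy, nz=80,
            x_extent=(-6.0, 6.0), y_extent=(-6.0, 6.0),
            z_extent=(max(depth - 1.5, 0.1), depth + 1.5),
        )
        vol = reconstruct_das(cd, med, grid, DASConfig(ray_model="refracted"))
        prof, coords = lateral_profile_through_peak(vol, axis=0)
        out.append(profile_fwhm(prof, coords))
    return out
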