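"""Spectral transform, layer extrapolation, NUFFT resampling, inversion,
pre-migration, and full-pipeline localization properties."""

import numpy as np
import pytest

from obskit.core import ChannelData, LayeredMedium, ReconGrid, SensorArray
from obskit.errors import GeometryError, UsageError
from obskit.forward import Phantom, PulseModel, simulate_channels
from obskit.psnufft import (
    NUFFTConfig,
    extrapolate_layers,
    forward_spectrum,
    invert_to_volume,
    pre_migrate,
    reconstruct,
    stolt_resample,
    stolt_resample_naive,
)


def tiny_array(nx=8, ny=8):
    return SensorArray.regular_grid(
        nx=nx, ny=ny, element_width=0.4, gap=0.1,
        center_frequency=7.8, fractional_bandwidth=1.0, sampling_rate=50.0,
    )


def no_pad_cfg(**kw):
    return NUFFTConfig(spatial_pad=1, time_pad=1, **kw)


class TestForwardSpectrum:
    def test_matches_brute_force_dft(self):
        """8×8×32 random field against the direct triple-sum transform."""
        rng = np.random.default_rng(0)
        arr = tiny_array()
        data = ChannelData(
            samples=rng.normal(size=(8, 8, 32)), t0=0.0, dt=0.02, geometry=arr
        )
        spec = forward_spectrum(data, no_pad_cfg())
        # direct evaluation of sum p(x,y,t) e^{-ikx x} e^{-iky y} e^{+iω t}
        xs = arr.element_centers.reshape(8, 8, 3)[:, 0, 0]
        ys = arr.element_centers.reshape(8, 8, 3)[0, :, 1]
        ts = data.times
        ref = np.einsum(
            "xyt,ax,by,wt->abw",
            data.samples.astype(complex),
            np.exp(-1j * np.outer(spec.kx, xs - xs[0])),
            np.exp(-1j * np.outer(spec.ky, ys - ys[0])),
            np.exp(1j * np.outer(spec.axis, ts)),
        )
        assert np.max(np.abs(spec.values - ref)) <= 1e-10 * np.max(np.abs(ref))

    def test_delta_input_has_flat_magnitude(self):
        arr = tiny_array()
        samples = np.zeros((8, 8, 32))
        samples[3, 5, 7] = 1.0
        data = ChannelData(samples=samples, t0=0.0, dt=0.02, geometry=arr)
        spec = forward_spectrum(data, no_pad_cfg())
        assert np.allclose(np.abs(spec.values), 1.0, atol=1e-12)

    def test_real_input_hermitian_in_omega(self):
        rng = np.random.default_rng(1)
        arr = tiny_array()
        data = ChannelData(
            samples=rng.normal(size=(8, 8, 32)), t0=0.0, dt=0.02, geometry=arr
        )
        v = forward_spectrum(data, no_pad_cfg()).values
        # P(−kx, −ky, −ω) = conj P(kx, ky, ω): flip all FFT axes
        flipped = v[
            np.ix_(
                (-np.arange(8)) % 8, (-np.arange(8)) % 8, (-np.arange(32)) % 32
            )
        ]
        assert np.allclose(flipped, np.conj(v), atol=1e-10)

    def test_inverse_round_trip(self):
        """Energy bookkeeping: forward then exact inverse reproduces input."""
        rng = np.random.default_rng(2)
        arr = tiny_array()
        data = ChannelData(
            samples=rng.normal(size=(8, 8, 32)), t0=0.0, dt=0.02, geometry=arr
        )
        spec = forward_spectrum(data, no_pad_cfg())
        back = np.fft.fft(np.fft.ifft2(spec.values, axes=(0, 1)), axis=2) / 32
        assert np.max(np.abs(back.real - data.samples)) <= 1e-10

    def test_non_planar_array_is_precondition_error(self):
        arr = tiny_array()
        arr.out_of_plane = arr.out_of_plane + 0.3
        data = ChannelData(
            samples=np.zeros((8, 8, 16)), t0=0.0, dt=0.02, geometry=arr
        )
        with pytest.raises(GeometryError, match="pre_migrate"):
            forward_spectrum(data)


class TestExtrapolation:
    @pytest.fixture
    def spec(self):
        rng = np.random.default_rng(3)
        arr = tiny_array()
        data = ChannelData(
            samples=rng.normal(size=(8, 8, 32)), t0=0.0, dt=0.02, geometry=arr
        )
        return forward_spectrum(data, no_pad_cfg())

    def test_zero_thickness_is_identity(self, spec):
        med = LayeredMedium([(np.inf, 1500.0)])
        out = extrapolate_layers(spec, med, 0)
        assert np.array_equal(out.values, spec.values)
        assert out.z_ref == 0.0

    def test_on_axis_phase_wraps_to_unity(self):
        """kx=ky=0, c=1500 m/s, d=1.5 mm, f=1 MHz: phase ωd/c = 2π exactly."""
        arr = tiny_array()
        nt = 50  # 1 MHz lands exactly on the ω grid (dt 0.02 µs)
        data = ChannelData(
            samples=np.ones((8, 8, nt)), t0=0.0, dt=0.02, geometry=arr
        )
        spec = forward_spectrum(data, no_pad_cfg())
        i_f = int(np.argmin(np.abs(spec.axis - 2 * np.pi * 1.0)))
        assert spec.axis[i_f] == pytest.approx(2 * np.pi, rel=1e-12)
        spec.values[:] = 1.0
        med = LayeredMedium([(1.5, 1500.0), (np.inf, 1500.0)])
        out = extrapolate_layers(spec, med, 1)
        # e^{-i·2π} = 1
        assert out.values[0, 0, i_f] == pytest.approx(1.0 + 0.0j, abs=1e-9)

    def test_layer_composition_is_exact(self, spec):
        """(d1, c) then (d2, c) equals the single slab (d1+d2, c)."""
        med_split = LayeredMedium([(1.2, 1500.0), (1.8, 1500.0), (np.inf, 1500.0)])
        med_single = LayeredMedium([(3.0, 1500.0), (np.inf, 1500.0)])
        a = extrapolate_layers(spec, med_split, 2)
        b = extrapolate_layers(spec, med_single, 1)
        scale = np.max(np.abs(b.values))
        assert np.max(np.abs(a.values - b.values)) <= 1e-12 * scale
        assert a.z_ref == b.z_ref == 3.0

    def test_out_of_range_layer_rejected(self, spec):
        med = LayeredMedium([(np.inf, 1500.0)])
        with pytest.raises(UsageError):
            extrapolate_layers(spec, med, 3)


class TestStoltResample:
    @pytest.fixture
    def spec(self):
        rng = np.random.default_rng(4)
        arr = tiny_array()
        data = ChannelData(
            samples=rng.normal(size=(8, 8, 64)), t0=0.0, dt=0.02, geometry=arr
        )
        return forward_spectrum(data, no_pad_cfg())

    def test_matches_naive_summation_oracle(self, spec):
        cfg = no_pad_cfg()
        kz = np.linspace(0.0, 40.0, 33)
        fast = stolt_resample(spec, 1500.0, cfg, kz)
        slow = stolt_resample_naive(spec, 1500.0, cfg, kz)
        scale = np.max(np.abs(slow.values))
        assert np.max(np.abs(fast.values - slow.values)) <= 1e-8 * scale

    def test_on_axis_jacobian_is_c(self, spec):
        """At kx=ky=0 the mapping is ω = c·kz with Jacobian exactly c for
        kz > 0 (and 0 at the kz = 0 degenerate point)."""
        c_mmus = 1.5
        dw = spec.axis[1] - spec.axis[0]
        kz = (dw / c_mmus) * np.arange(12)  # ω* lands exactly on grid nodes
        out = stolt_resample(spec, 1500.0, no_pad_cfg(), kz)
        assert out.values[0, 0, 0] == 0.0  # Jacobian c·kz/|k| vanishes at kz=0
        for j in range(1, 12):
            expected = c_mmus * spec.values[0, 0, j]
            assert out.values[0, 0, j] == pytest.approx(expected, rel=1e-9)

    def test_grid_nodes_interpolate_identically(self, spec):
        """Samples landing exactly on ω nodes reproduce the node values."""
        dw = spec.axis[1] - spec.axis[0]
        c_mmus = 1.5
        kz = (dw / c_mmus) * np.arange(10)  # on-axis ω* lands on grid nodes
        out = stolt_resample(spec, 1500.0, no_pad_cfg(), kz)
        for j in range(1, 10):
            expected = c_mmus * spec.values[0, 0, j]
            assert out.values[0, 0, j] == pytest.approx(expected, rel=1e-9)


class TestInversion:
    def make_kz_spec(self, values, kz, arr):
        from obskit.psnufft import SpectralField

        return SpectralField(
            values=values, kx=2 * np.pi * np.fft.fftfreq(8, 0.5),
            ky=2 * np.pi * np.fft.fftfreq(8, 0.5), axis=kz, domain="kz",
            z_ref=0.0, x0=-1.75, y0=-1.75, dx=0.5, dy=0.5,
        )

    def test_zero_spectrum_gives_zero_volume(self):
        kz = np.linspace(0, 30, 16)
        spec = self.make_kz_spec(np.zeros((8, 8, 16), complex), kz, None)
        grid = ReconGrid(nx=8, ny=8, nz=10, x_extent=(-2, 2), y_extent=(-2, 2),
                         z_extent=(0.0, 2.0))
        vol = invert_to_volume(spec, grid, (0.0, 5.0))
        assert np.all(vol.voxels == 0)

    def test_output_is_real(self):
        rng = np.random.default_rng(5)
        kz = np.linspace(0, 30, 16)
        vals = rng.normal(size=(8, 8, 16)) + 1j * rng.normal(size=(8, 8, 16))
        spec = self.make_kz_spec(vals, kz, None)
        grid = ReconGrid(nx=8, ny=8, nz=10, x_extent=(-2, 2), y_extent=(-2, 2),
                         z_extent=(0.0, 2.0))
        vol = invert_to_volume(spec, grid, (0.0, 5.0))
        assert np.isrealobj(vol.voxels)

    def test_empty_layer_interval_rejected(self):
        kz = np.linspace(0, 30, 16)
        spec = self.make_kz_spec(np.zeros((8, 8, 16), complex), kz, None)
        grid = ReconGrid(nx=8, ny=8, nz=10, x_extent=(-2, 2), y_extent=(-2, 2),
                         z_extent=(0.0, 2.0))
        with pytest.raises(UsageError):
            invert_to_volume(spec, grid, (5.0, 5.0))


class TestPreMigration:
    def test_planar_input_is_noop(self, point_channels):
        data, _ = point_channels
        out = pre_migrate(data, np.zeros(data.geometry.n_elements), 1500.0)
        assert np.array_equal(out.samples, data.samples)

    def test_uniform_shift_is_exact_delay(self, point_channels):
        """Δz = 0.75 mm at c = 1500 m/s delays every trace by 0.5 µs."""
        data, _ = point_channels
        dz = np.full(data.geometry.n_elements, 0.75)
        out = pre_migrate(data, dz, 1500.0)
        shift_samples = 0.5 / data.dt
        assert shift_samples == int(shift_samples)
        s = int(shift_samples)
        orig = data.samples[:, :, : -s or None]
        moved = out.samples[:, :, s:]
        # compare away from the wrap-around edges
        assert np.allclose(moved[:, :, 16:-16], orig[:, :, 16:-16], atol=1e-6)

    def test_bent_array_recovers_point(self, homogeneous_medium, pulse):
        """Cylinder-bent aperture (R = 40 mm): redatum then reconstruct."""
        arr = tiny_array(16, 16)
        R = 40.0
        bent = SensorArray(
            element_centers=arr.element_centers.copy(), nx=16, ny=16,
            element_width=0.4, element_height=0.4, gap=0.1,
            center_frequency=7.8, fractional_bandwidth=1.0, sampling_rate=50.0,
        )
        dz = R - np.sqrt(R**2 - bent.element_centers[:, 0] ** 2)
        bent.element_centers[:, 2] = dz  # elements bent toward the tissue
        src = (0.5, -0.5, 4.0)
        phantom = Phantom(point_sources=[(src, 1.0)])
        data = simulate_channels(phantom, bent, homogeneous_medium, pulse)
        bent.out_of_plane = dz
        flat = pre_migrate(data, dz, 1500.0)
        grid = ReconGrid(nx=64, ny=64, nz=60, x_extent=(-4, 4), y_extent=(-4, 4),
                         z_extent=(2.5, 5.5))
        vol = reconstruct(flat, homogeneous_medium, grid, envelope=True)
        peak = vol.peak_position()
        for i in range(3):
            assert abs(peak[i] - src[i]) <= 2.5 * vol.spacing[i]


class TestFullPipeline:
    def test_point_source_localization(self, homogeneous_medium, pulse):
        """Reconstructed peak within one voxel of truth at SNR 20 dB."""
        arr = tiny_array(16, 16)
        rng = np.random.default_rng(9)
        for _ in range(6):
            src = (
                float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2)),
                float(rng.uniform(3, 6)),
            )
            phantom = Phantom(point_sources=[(src, 1.0)])
            clean = simulate_channels(phantom, arr, homogeneous_medium, pulse)
            snr_sd = np.abs(clean.samples).max() / 10 ** (20 / 20)
            data = simulate_channels(
                phantom, arr, homogeneous_medium, pulse,
                noise_sd=snr_sd, seed=int(rng.integers(1 << 30)),
            )
            grid = ReconGrid(
                nx=64, ny=64, nz=80, x_extent=(-4, 4), y_extent=(-4, 4),
                z_extent=(2.0, 7.0),
            )
            vol = reconstruct(data, homogeneous_medium, grid, envelope=True)
            peak = vol.peak_position()
            for i in range(3):
                assert abs(peak[i] - src[i]) <= 1.5 * vol.spacing[i] + 1e-9

    def test_two_layer_localization(self, two_layer_medium, pulse):
        arr = tiny_array(16, 16)
        src = (1.0, 0.5, 5.0)
        phantom = Phantom(point_sources=[(src, 1.0)])
        data = simulate_channels(phantom, arr, two_layer_medium, pulse)
        grid = ReconGrid(nx=64, ny=64, nz=80, x_extent=(-4, 4), y_extent=(-4, 4),
                         z_extent=(2.0, 7.0))
        vol = reconstruct(data, two_layer_medium, grid, envelope=True)
        peak = vol.peak_position()
        for i in range(3):
            assert abs(peak[i] - src[i]) <= 1.5 * vol.spacing[i] + 1e-9

    def test_single_layer_degenerates_to_plain_stolt(self, homogeneous_medium, pulse):
        """L=1 reconstruction equals a dedicated single-layer migration
        (forward spectrum → Stolt map → inversion, no extrapolation stage)."""
        arr = tiny_array()
        phantom = Phantom(point_sources=[((0.5, 0.0, 3.0), 1.0)])
        data = simulate_channels(phantom, arr, homogeneous_medium, pulse)
        grid = ReconGrid(nx=32, ny=32, nz=40, x_extent=(-2, 2), y_extent=(-2, 2),
                         z_extent=(1.0, 5.0))
        cfg = NUFFTConfig()
        vol = reconstruct(data, homogeneous_medium, grid, cfg)

        # independent single-layer path: no extrapolate_layers call at all,
        # same kz lattice construction as the pipeline
        from scipy.fft import next_fast_len

        spec = forward_spectrum(data, cfg)
        dz = grid.spacing[2]
        n_fft = next_fast_len(int(np.ceil(4.0 * grid.z_extent[1] / dz)))
        dkz = 2 * np.pi / (n_fft * dz)
        kz_max = min(np.pi / dz, np.max(np.abs(spec.axis)) / 1.5)
        kz = dkz * np.arange(int(np.clip(kz_max / dkz, 8, n_fft)))
        spec_kz = stolt_resample(spec, 1500.0, cfg, kz)
        ref = invert_to_volume(spec_kz, grid, (0.0, np.inf))
        scale = np.max(np.abs(ref.voxels))
        assert np.max(np.abs(vol.voxels - ref.voxels)) <= 1e-10 * scale
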