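"""Forward oracle: arrivals, linearity, determinism, phantoms, protocols."""

import numpy as np
import pytest

from obskit.core import LayeredMedium, ReconGrid
from obskit.errors import UsageError, ValidationError
from obskit.forward import (
    Phantom,
    ProtocolSpec,
    PulseModel,
    make_phantom,
    simulate_channels,
    simulate_trend_series,
)
from obskit.raypaths import fermat_scan_oracle, travel_time


class TestArrivalTimes:
    def test_on_axis_single_layer_arrival(self, small_array, homogeneous_medium, pulse):
        # nearest element sits at (0.25, 0.25); use a source right above it
        src = (0.25, 0.25, 6.0)
        phantom = Phantom(point_sources=[(src, 1.0)])
        data = simulate_channels(phantom, small_array, homogeneous_medium, pulse)
        e = np.argmin(
            np.linalg.norm(small_array.element_centers[:, :2] - src[:2], axis=1)
        )
        ix, iy = divmod(int(e), small_array.ny)
        trace = data.samples[ix, iy]
        # envelope centre of the N-shaped pulse = travel time d/c = 4 µs
        t_peak = data.times[np.argmax(np.abs(trace))]
        assert t_peak == pytest.approx(6.0 / 1.5, abs=2 * data.dt + pulse.sigma_t)

    def test_normal_incidence_two_layers_sums_transits(self, two_layer_medium):
        t = travel_time((0, 0, 0), (0, 0, 5.0), two_layer_medium, "refracted")
        expected = 2.0 / 1.65 + 3.0 / 1.48
        assert t == pytest.approx(expected, rel=1e-10)

    def test_oblique_two_layer_matches_fermat_scan(self, two_layer_medium):
        rng = np.random.default_rng(11)
        for _ in range(20):
            e = (rng.uniform(-5, 5), rng.uniform(-5, 5), 0.0)
            v = (rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(2.5, 9.0))
            t_fast = travel_time(e, v, two_layer_medium, "refracted")
            t_scan = fermat_scan_oracle(e, v, two_layer_medium, n_scan=10_000)
            assert t_fast == pytest.approx(t_scan, abs=1e-4)

    def test_reciprocity(self, two_layer_medium):
        # horizontal offset is all that matters: swapping lateral positions of
        # element and voxel leaves the travel time unchanged
        a = travel_time((1.0, -2.0, 0), (4.0, 3.0, 6.0), two_layer_medium)
        b = travel_time((4.0, 3.0, 0), (1.0, -2.0, 6.0), two_layer_medium)
        assert a == pytest.approx(b, rel=1e-12)

    def test_source_above_plane_rejected(self, homogeneous_medium):
        with pytest.raises(ValidationError):
            travel_time((0, 0, 0), (0, 0, -1.0), homogeneous_medium)


class TestSimulateChannels:
    def test_empty_phantom_gives_zero_channels(
        self, small_array, homogeneous_medium, pulse
    ):
        data = simulate_channels(
            Phantom(), small_array, homogeneous_medium, pulse, n_times=128
        )
        assert np.all(data.samples == 0)

    def test_linearity_in_amplitude(self, small_array, homogeneous_medium, pulse):
        p1 = Phantom(point_sources=[((0.5, 0.5, 3.0), 1.0)])
        p2 = Phantom(point_sources=[((0.5, 0.5, 3.0), 2.0)])
        d1 = simulate_channels(p1, small_array, homogeneous_medium, pulse)
        d2 = simulate_channels(p2, small_array, homogeneous_medium, pulse)
        assert np.allclose(d2.samples, 2.0 * d1.samples)

    def test_seed_determinism(self, small_array, homogeneous_medium, pulse):
        p = Phantom(point_sources=[((0.0, 0.0, 3.0), 1.0)])
        d1 = simulate_channels(
            p, small_array, homogeneous_medium, pulse, noise_sd=0.1, seed=42
        )
        d2 = simulate_channels(
            p, small_array, homogeneous_medium, pulse, noise_sd=0.1, seed=42
        )
        assert np.array_equal(d1.samples, d2.samples)

    def test_source_behind_plane_rejected(
        self, small_array, homogeneous_medium, pulse
    ):
        p = Phantom(
            point_sources=[((0.0, 0.0, 0.0), 1.0)],
            bounds=((-5, 5), (-5, 5), (-2, 5)),
        )
        p.point_sources = [((0.0, 0.0, -1.0), 1.0)]  # bypass bounds check
        with pytest.raises(ValidationError):
            simulate_channels(p, small_array, homogeneous_medium, pulse)


class TestPhantom:
    def test_make_phantom_single_point(self):
        ph = make_phantom({"points": [{"position": [3.5, 0.0, 5.0]}]})
        assert len(ph.point_sources) == 1
        assert ph.point_sources[0][0] == (3.5, 0.0, 5.0)

    def test_out_of_volume_rejected(self):
        with pytest.raises(ValidationError):
            make_phantom(
                {"points": [{"position": [50.0, 0.0, 5.0]}]}
            )

    def test_voxelized_tube_volume_matches_analytic(self):
        # straight tube: lattice-cell count × cell volume ≈ π r² L
        ph = Phantom(
            vessels=[(np.array([[0.0, 0.0, 5.0], [6.0, 0.0, 5.0]]), 0.5, 1.0)]
        )
        pts, amps = ph.as_point_sources(spacing=0.08)
        lattice_volume = amps.sum()  # amplitude 1 × cell volume each
        analytic = np.pi * 0.5**2 * 6.0 + (4 / 3) * np.pi * 0.5**3  # + end caps
        assert lattice_volume == pytest.approx(analytic, rel=0.05)

    def test_rasterize_marks_tube_interior(self):
        ph = Phantom(
            vessels=[(np.array([[-2.0, 0.0, 5.0], [2.0, 0.0, 5.0]]), 0.5, 2.0)]
        )
        grid = ReconGrid(nx=40, ny=40, nz=40, x_extent=(-4, 4), y_extent=(-4, 4),
                         z_extent=(3, 7))
        vol = ph.rasterize(grid)
        ix = np.argmin(np.abs(grid.x))
        iy = np.argmin(np.abs(grid.y))
        iz = np.argmin(np.abs(grid.z - 5.0))
        assert vol[ix, iy, iz] == 2.0
        assert vol[0, 0, 0] == 0.0


class TestTrendGenerator:
    def test_hypoxia_period_is_230_s(self):
        spec = ProtocolSpec(kind="hypoxia_cycle")
        ts = simulate_trend_series(spec, duration=920.0, dt=0.5)
        v = ts.values - ts.values.mean()
        # autocorrelation peak at one cycle
        ac = np.correlate(v, v, mode="full")[len(v) - 1 :]
        lag = np.argmax(ac[300:700]) + 300  # search away from zero lag
        assert lag * 0.5 == pytest.approx(230.0, abs=1.0)
        # low phase lasts 50 s per cycle
        low_frac = np.mean(ts.values < ts.values.mean())
        assert low_frac == pytest.approx(50.0 / 230.0, abs=0.01)

    def test_venous_lag_shifts_edges(self):
        art = simulate_trend_series(
            ProtocolSpec(kind="hypoxia_cycle"), 460.0, 0.5, roi="artery"
        )
        vein = simulate_trend_series(
            ProtocolSpec(kind="hypoxia_cycle", venous_delay=10.0), 460.0, 0.5,
            roi="vein",
        )
        def falling_edge_after(ts, t_min):
            d = np.diff(ts.values)
            idx = np.where((d < 0) & (ts.timestamps[:-1] > t_min))[0]
            return ts.timestamps[idx[0]]

        fall_a = falling_edge_after(art, 100.0)
        fall_v = falling_edge_after(vein, 100.0)
        assert fall_v - fall_a == pytest.approx(10.0, abs=0.5 + 1e-9)

    def test_zero_rate_decay_is_constant(self):
        ts = simulate_trend_series(
            ProtocolSpec(kind="agent_decay", decay_rate=0.0), 100.0, 1.0
        )
        assert np.ptp(ts.values) == 0

    def test_decay_factor_at_2000_s(self):
        spec = ProtocolSpec(kind="agent_decay", decay_rate=3.6e-4, baseline=1.0)
        ts = simulate_trend_series(spec, duration=2001.0, dt=1.0)
        # closed form: e^(−0.72) ≈ 0.4868 before any baseline mixing
        assert ts.values[2000] / ts.values[0] == pytest.approx(
            np.exp(-0.72), rel=1e-9
        )

    def test_occlusion_step_sizes(self):
        vein = simulate_trend_series(ProtocolSpec(kind="occlusion_vein"), 200.0, 1.0)
        art = simulate_trend_series(ProtocolSpec(kind="occlusion_artery"), 200.0, 1.0)
        assert vein.values.max() / vein.values.min() == pytest.approx(1.23)
        assert art.values.min() / art.values.max() == pytest.approx(0.63)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(UsageError):
            ProtocolSpec(kind="valsalva")


class TestPulseModel:
    def test_bandwidth_at_minus6db(self):
        pulse = PulseModel(7.8, 1.0)
        t = np.arange(-2.0, 2.0, 1e-3)
        w = pulse.waveform(t)
        f = np.fft.rfftfreq(len(t), 1e-3)
        mag = np.abs(np.fft.rfft(w))
        peak = mag.max()
        band = f[mag >= 0.5 * peak]
        frac_bw = (band.max() - band.min()) / 7.8
        assert frac_bw == pytest.approx(1.0, abs=0.06)
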