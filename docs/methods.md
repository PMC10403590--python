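# Methods

This note records the models behind `obskit`, the assumptions they make, the
defaults and why, and what the packaged synthetic studies can and cannot say
about real data.

## Coordinates, units, conventions

Right-handed coordinates with the sensor plane at z = 0 and z positive into
tissue; lengths in mm, time in µs, frequency in MHz (sound speeds are
accepted in m/s and converted). Spectra use the analysis kernels
e^(−i kx x) e^(−i ky y) e^(+i ω t). With that temporal sign, downward
continuation of the recorded upgoing wavefield is multiplication by
e^(−i kz d) with kz = √((ω/c)² − kx² − ky²) ≥ 0 for ω > 0, and the image
synthesis kernel is e^(−i kz z); this is verified by round trips (a source at
depth z_s reconstructs at +z_s). "−6 dB" resolution widths are measured at
exact half-maximum (−6.02 dB).

## Layered-medium Fourier reconstruction (PS-NUFFT)

Per layer l the pipeline is: 3D FFT of the zero-padded channel plane →
cascade of phase shifts through layers 1…l−1, each with its own speed,
evanescent components (kx²+ky² > (ω/c_l)²) set to zero → spectral change of
variables ω(kx,ky,kz) = c_l·√(kx²+ky²+kz²) with Jacobian c_l·kz/√(·), using
a Kaiser-windowed sinc basis (half-width 6 ω-samples, β = 6, evaluated from
a dense lookup table that is exact at integer offsets) → inverse lateral FFT
(zero-padding the kx/ky spectrum provides image up-sampling at no extra
model cost) and an FFT inversion along kz restricted to the layer's depth
interval. The kz lattice is chosen commensurate with the requested axial
voxel size so the axial inversion runs on the FFT path; an arbitrary kz grid
falls back to direct evaluation.

Choices worth knowing:

* Evanescent components are zeroed rather than exponentially grown — growth
  amplifies noise and imaging uses propagating waves only.
* The 1/(8π³) normalization of the continuous transform is absorbed; all
  amplitudes are relative.
* Time axis is zero-padded 2× (wrap-around suppression) and the aperture 2×
  (default `spatial_pad=2`); the lateral image extent is therefore fixed by
  the padded aperture, with the requested grid controlling sampling density.
* Down-sampling (D_p) of the kz spectrum is exposed but defaults to 1.
* Pre-migration for bent apertures applies per-trace delays Δt = Δz/c₁ as
  exact band-limited Fourier shifts; valid for displacements small against
  the aperture (warning above 1 mm). Registration of tracked surface
  coordinates provides the Δz via a least-squares reference plane.

## Delay-and-sum baseline

Time-domain beamforming with pre-tabulated travel times over (depth,
horizontal offset) — layered travel times depend only on those two
coordinates — and a compiled inner loop. The refracted model solves Fermat's
problem exactly by bisection on the ray parameter (monotone horizontal
offset); the straight model integrates slowness along the chord. Envelope
default is the analytic-signal magnitude, standard for resolution
metrology; apodization (Hann) is optional and off by default.

## The packaged layered-phantom benchmark (`fixtures.run_comparison`)

Two-layer medium (3 mm at 1700 m/s over half-infinite 1480 m/s), a point
absorber at (3.5, 0, 5) mm plus a Y-shaped vessel (radius 0.4 mm), recorded
by a dense 40×40, 0.25 mm-pitch planar aperture at 7.8 MHz/100% bandwidth
and 50 MHz sampling, with white channel noise of 4.5% of the peak channel
amplitude. The Fourier method uses the true layered model; the DAS arm is
deliberately run the classical way — straight rays and a single assumed
1540 m/s speed — because that homogeneous-medium shortcut is what the
layered method exists to correct (with exact refracted delays on the same
dense, point-sampled aperture, DAS is sharper than any pitch-band-limited
Fourier method, and the comparison would be vacuous). Two documented
consequences:

* The wearable's own 6×6, 1.66 mm-pitch grid band-limits Fourier
  reconstruction to ±π/pitch ≈ ±1.9 rad/mm, i.e. a ≥2 mm lateral FWHM, so
  the benchmark samples the same ~10 mm aperture densely instead; results on
  the dense aperture do not transfer to the sparse device grid.
* Metrics: −6 dB FWHM of the lateral profile through the point image; CNR =
  20·log₁₀(|μ_s−μ_b|/σ_b) and gCNR (100 shared bins) over fixture ROIs —
  signal = vessel interior, background = a clean slab above the sources.
  The classical DAS arm defocuses to ≈0.5 mm here rather than the ~1.5 mm a
  sparser/more error-prone configuration would show; a dense-aperture DAS
  caustic stays locally sharp under moderate speed errors, and we do not
  degrade the implementation to widen it.

## Device resolution study (`fixtures.device_resolution_study`)

Point targets at 2, 5 and 10 mm depth seen by the real 6×6 grid with the
finite 1.51 mm element faces sampled 7×7 (sub-aperture averaging produces
the element directivity), reconstructed in the time domain with refracted
delays. At 7.8 MHz a 1.51 mm face accepts only ~±7°, so the usable
sub-aperture — hence lateral resolution — is set by the element size
(~1.1 mm depth-averaged), not by the 10 mm array width. This models the
physical point-target characterization of the device; the Fourier path on
the same data is pitch-limited (≈1.9 mm) and is not the right model for
that measurement.

## Monte Carlo illumination

Photon-packet transport in a homogeneous dermis slab: exponential steps with
µt = µa+µs, Henyey–Greenstein scattering, absorption-weight deposition at
interaction points, Russian roulette below 10⁻⁴ (survival 0.1). Dermis at
532 nm: µs = 357 cm⁻¹, µa = 0.46 cm⁻¹; anisotropy g = 0.9 and n = 1.4 are
typical-dermis assumptions (exposed in `OpticalMedium`). Refractive
boundaries are not modelled: photons crossing the surfaces escape. The three
source geometries: 5×5 converging focal spots on a 1.99 mm pitch (entry
radius 0.2 mm, focus 0.5 mm deep); a 4×4 mm collimated centre window;
edge-entry side illumination at 45°. The effective-illumination fraction at
a depth is the footprint fraction within −20 dB (intensity) of the slice
maximum; the slice is smoothed by a 1-voxel Gaussian so the estimate is
stable against shot noise. Default tallies: 0.1 mm voxels over a 12×12×3 mm
box. What this does not capture: layered skin optics, melanin/epidermis
absorption, refractive-index mismatch at the surface, and lens aberrations —
so passing tests show geometry *ranking* and uniformity trends, not absolute
fluence.

## Acoustic receive fields

Reciprocal single-frequency Rayleigh integral of e^(ikr)/r over the element
face, evaluated exactly as a 2D FFT convolution of the aperture indicator
with the free-space kernel at ≥20 samples per wavelength. The array AFOV
can superimpose per-element magnitudes (sensitivity coverage; the default)
or the complex fields ("coherent": what the array records with all channels
summed — includes inter-element interference). Uniformity statistics
(mean-vs-max in dB, s.d. of pixel levels) are evaluated over the −12 dB
effective mask or over the device footprint. The device study uses the
coherent sum over the footprint at c = 1500 m/s, which reproduces the
published ≈ −6.5 dB mean-vs-max at 1 mm and the improvement of uniformity
with depth. The single-element −12 dB effective area computed this way is
≈2.8 mm² at 1 mm — close to the device's measured 3.17 mm² but well below
the published simulated 5.5 mm²; since intensity-dB and amplitude-dB
coincide for ratios, no convention choice closes that gap and we report
what the exact integral gives. Axial resolution uses the pulse-length
criterion `criterion·c/(2B)` with the conservative two-cycle default
criterion = 2 (→ 192 µm ≈ 0.2 mm for 7.8 MHz, 100% bandwidth, 1500 m/s);
the constant is configurable.

## Physiological protocols and fits

The trend generator reproduces the published protocol shapes: hypoxia cycles
of 230 s (50 s low + 180 s normal oxygen) with a configurable venous lag
(default 10 s — the published traces show a "noticeable" but unquantified
venous delay); occlusion steps of +23% (vein) and −37% (artery); and
exponential washout `B·[(1−m)e^(−kt) + m]` with default k = 3.6×10⁻⁴ s⁻¹.
The static background fraction m reconciles the two published facts that the
blood ROI fell 28% at 2000 s while pure clearance at that k gives 51%: m ≈
0.45 matches both, and tissue clearance of −10% at 2000 s corresponds to
k ≈ 5.3×10⁻⁵ s⁻¹.

Fits: sO₂ calibration is an ordinary least-squares line (mV per % sO₂).
Agent decay divides the blood trend by the start-normalized tissue baseline
(removing shared illumination/coupling drift) and fits A·e^(−kt) + C by
nonlinear least squares seeded from a log-linear fit; the offset term
absorbs residual static signal. Venous compliance is the per-interval finite
difference ΔR/ΔP with points at ≤40 mmHg excluded (below resting venous
pressure the vessel flattens); on the published ratio table
(102/108/114% at 50/80/110 mmHg) this gives 0.200 %/mmHg per interval —
the published 0.196/0.185 come from unrounded source data and are matched
only at rounding level. FMD converts the relative signal change at the
post-release peak via √(1+p_A) − 1 (signal ∝ cross-sectional area).

All in-vivo numbers enter only as generator parameters verified by
parameter recovery; nothing here reproduces animal or human measurements.

## Problem sizes and budgets

The packaged studies are sized for a single CPU: the benchmark comparison
reconstructs 128×128×150 voxels from 1600 channels (≈50 s total for both
methods); unit tests use 16×16 apertures and 10⁵-range photon counts; the
acceptance script runs the Monte Carlo stage at 10⁶ photons. Runtime-scaling
checks time n×n×96 grids with n×n elements across n = 24…64 and extrapolate
the fitted power laws to the published working size n = 128.
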