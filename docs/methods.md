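# Methods

## Signal model

fsikit simulates structured *detection*: the scene's image is modulated by a
pattern on a binary spatial light modulator before a bucket detector, rather
than the illumination being structured. The forward model is the inner
product D = Σ_xy I(x,y)·P(x,y) + n. Pixel and frequency coordinates are
0-based; the DFT convention is an unnormalized forward kernel
e^{−j2π(ux/M + vy/N)} with 1/(MN) on the inverse. Under this convention the
three-step phase-shifting combination (2D₀ − D₁ − D₂) + √3 j (D₁ − D₂)
equals exactly 1.5 × the forward DFT coefficient for noiseless grayscale
patterns; the 1.5 is divided out at spectrum assembly, which fixes the
package's radiometric scale (reconstructions of noiseless full acquisitions
equal the scene in its own units).

Assumptions: the scene is static over an acquisition; the modulator is
linear (grayscale) or binary (dithered); the detector is linear with
additive noise; the scintillator in the x-ray modality is a fixed linear
converter. No optics PSF is modeled, so simulated resolution reflects the
sampling/reconstruction kernel only — values are not comparable to a
physical instrument's optics-limited numbers.

## Sampling plans

Hermitian symmetry of real scenes means one representative per conjugate
pair suffices. The canonical half-plane keeps 0 < v < N/2 unconditionally
and breaks ties on the self-mirrored columns v ∈ {0, N/2} by u ≤ M − u.
Circular sampling orders representatives by wrap-around radius
r = √(min(u, M−u)² + min(v, N−v)²), ties by (u, v); selection stops when the
covered fraction of the M·N bins reaches the requested ratio, counting a
non-self-conjugate selection as two bins (itself plus its implied
conjugate). This makes ratio = 1 exactly reachable and matches how sampling
ratios are quoted in the single-pixel-imaging literature; a
`conjugate_counting=False` flag switches to counting only displayed
coefficients for comparison with that convention. Deterministic ordering
makes lower-ratio plans strict prefixes of higher-ratio ones.

Whether a real system measures the DC term or estimates it separately is an
open question; here DC is always the first plan entry, since radius 0 sorts
first and reconstruction needs the mean.

## Dithering

Floyd–Steinberg error diffusion with the classic 7/16, 3/16, 5/16, 1/16
kernel, serpentine scan (mirrored kernel on right-to-left rows, the common
anti-streak choice), threshold ≥ 0.5, and quantization error dropped at grid
borders. The scan order is fixed so binary patterns are bit-exact
reproducible. Dropped border error bounds the mean discrepancy between a
binary pattern and its grayscale source by (M+N)/(M·N). Border error
dropping also leaves a one-to-two-pixel artifact band at the field edge of
dithered reconstructions; evaluation profiles therefore stay clear of the
border.

## Phantoms (what the generator emulates — and what it does not)

* **Wire (x-ray)**: Beer–Lambert transmission through a circular
  cross-section chord, t(a) = exp(−od·√(1 − (a/R)²)), rendered by exact
  pixel-footprint averaging (the footprint projects onto the wire normal as
  a convolution of two box kernels, applied to a finely sampled profile at
  0.002 px). Default central-chord optical depth 6.0 — a metal wire under a
  50-kV tube is effectively opaque. No beam hardening, cone-beam geometry,
  or scintillator blur.
* **Dilution row (fluorescence)**: discs at gain × concentration with 4×4
  subpixel edge coverage; blank water well at zero; default two-fold series
  11.86 → 0.74 nmol/ml plus blank, blank leftmost. Emission is strictly
  linear in concentration — no self-quenching, inner-filter effects, or
  excitation inhomogeneity.
* **Buried tube (fluorescence depth)**: a stripe of width diameter/pitch
  whose amplitude decays as exp(−μ_eff·d), μ_eff = √(3·μa·(μa+μs′)) — the
  diffusion-regime effective attenuation (≈1.053 cm⁻¹ at the default
  μa = 0.03, μs′ = 12.3 cm⁻¹) — plus a lateral Gaussian spread
  σ = 0.5·d (mm) emulating diffusive blur. This scalar model is sufficient
  for detectability studies; it is not a photon-transport simulation, and
  depth-dependent spectral changes are ignored.

Passing tests on these phantoms demonstrates the correctness of the
acquisition/reconstruction/evaluation machinery, not the fidelity of any
physical instrument: real data add optics blur, nonuniform illumination,
detector nonlinearity and structured background that the generator omits.

## Noise

The noise term is split into an ambient offset (constant across a triplet —
exactly the component the phase-shifting weights cancel), independent
per-reading Gaussian read noise, and optional Poisson resampling of the
clean bucket signal. All draws come from one generator seeded per
experiment, so runs are bit-reproducible. Defaults: the wire and dilution
presets use Gaussian sigma = 0.1% of the mean bucket reading (an averaged
PMT signal regime); the depth study uses a fixed sigma of 2.5 detector
units, calibrated once by a CNR sweep so the Rose-criterion detectability
limit falls between 4 and 6 mm of medium, and frozen thereafter as a
regression fixture.

## Evaluation procedures

* **Resolution**: bilinear line profile at unit-pixel spacing, Gaussian
  least-squares fit (scipy curve_fit). Initialization: baseline = median,
  amplitude = extremum − baseline, center = extremum, sigma = half the
  width above half-extremum; polarity (dip vs peak) is the sign of the
  extremum farthest from the median. FWHM = 2√(2 ln 2)·σ·pitch.
* **Sensitivity**: 5×5 ROI means per well; OLS calibration with
  R² = 1 − SS_res/SS_tot (defined as 0 for constant responses); detection
  limit = lowest concentration whose ROI mean exceeds the blank mean by
  three blank standard deviations (the blank ROI's own pixel statistics).
* **Depth detectability**: CNR = (mean_tube − mean_bg)/sd_bg on geometry
  masks with a 6-mm guard band around the stripe (shrunk on small fields);
  detectable iff CNR ≥ 5 (Rose criterion — "clearly distinguished" made
  explicit and configurable). The CNR is invariant to affine intensity
  rescaling of the reconstruction.

## Numerical choices

* Spectrum assembly forces self-conjugate bins real (their imaginary part
  is pure noise; logged at debug level) and zero-fills unmeasured bins — a
  plain inverse transform, no compressed-sensing completion.
* Inverse transforms assert an imaginary residue below 1e−9 of the image
  maximum before discarding it; non-Hermitian spectra are rejected.
* PSNR = 10·log₁₀(peak²/MSE) with peak taken from the reference scene.
* The dither-fidelity regression gate is 30 dB mean PSNR at full sampling
  over a fixed suite of ten seeded smooth phantoms (Gaussian-filtered white
  noise, σ = 6 px, rescaled to [0, 1]); the package's first benchmark run
  measured 31.2 dB. The gate guards the dither/acquisition path against
  regressions and claims nothing about hardware.
* Measurement CSVs are written with 17-significant-digit floats and parsed
  with round-trip precision, so replay is bit-identical.

## Problem sizes

Full-resolution checks (dither fidelity, PSNR-vs-ratio monotonicity, the
bench presets) run at the reference 96×128 geometry; exactness and oracle
checks run on grids from 4×4 to 24×32, where brute-force enumeration,
per-coefficient DFT comparison, and 50-scene identity sweeps are cheap.

## Known limitations

Resolution and sensitivity numbers from the virtual instrument are
simulation-level: they quantify the sampling strategy and noise regime, not
any optical train. The depth phantom's blur model is heuristic
(σ = 0.5·d). Tilted-modulator projective geometry, DMD timing, hardware
control, and iterative or learned reconstruction are out of scope.
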