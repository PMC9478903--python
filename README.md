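# fsikit

Structured-detection **Fourier single-pixel imaging (FSI)**, end to end and
without hardware: pattern synthesis and binarization, a virtual dual-modality
(x-ray transmission / fluorescence emission) instrument with a bucket-detector
forward model, three-step phase-shifting spectrum recovery, inverse-DFT
reconstruction, and the bench evaluation procedures used to characterize such
systems — spatial resolution, fluorophore sensitivity, and imaging depth.

It is written for people building or studying single-pixel imagers (e.g. a
DMD + photomultiplier behind a CsI(Tl) scintillator, which lets one visible
detector serve both x-ray and fluorescence modalities): you can prototype
sampling strategies, binarization, and noise regimes in simulation, and you
can replay measurement sets recorded as CSV through the same reconstruction
path.

## The method

An M×N scene I(x, y) is probed one Fourier coefficient at a time. For a
coefficient (u, v), three fringe patterns with initial phases
φ ∈ {0, 2π/3, 4π/3} are displayed:

```
P_φ(x, y; u, v) = 1/2 + 1/2 · cos(2πux/M + 2πvy/N + φ)
```

A bucket (single-pixel) detector returns D_φ = Σ_xy I·P_φ + n. The three
responses combine to a complex coefficient

```
F(u, v) = (2·D_0 − D_{2π/3} − D_{4π/3}) + √3 · j · (D_{2π/3} − D_{4π/3})
```

which equals exactly 3/2 times the scene's unnormalized forward DFT
coefficient for noiseless grayscale patterns (fsikit divides the 3/2 out, so
spectra compare directly to `numpy.fft.fft2`). The weights (2, −1, −1) and
(0, 1, −1) sum to zero, so any constant pedestal in the readings — ambient
light, scintillator afterglow — cancels identically.

Real scenes have Hermitian spectra, so only one member of each conjugate pair
is measured; the **circular sampling** strategy takes the lowest centered
radial frequencies first until a target coverage (default 14%) is reached.
Patterns are **Floyd–Steinberg dithered** (serpentine scan) into the binary
masks a micromirror device can display. Reconstruction is the plain inverse
DFT of the Hermitian-completed, zero-filled spectrum.

## Worked example

`examples/` holds one short script per capability. The imaging-depth study
(`python examples/imaging_depth.py`) buries a 1-mm fluorescent tube at
increasing depth in a scattering medium (μa = 0.03 cm⁻¹, μs′ = 12.3 cm⁻¹),
images it at 96×128 px / 0.52 mm pitch / 14% circular sampling with dithered
patterns, and prints:

```
mu_eff = 1.053 /cm
depth [mm]      CNR  detectable
         2    15.91        True
         4     6.37        True
         6     4.18       False
         8     2.16       False
```

CNR is the tube-versus-background contrast-to-noise ratio of the
reconstruction; by the Rose criterion (CNR ≥ 5) the tube is detectable down
to 4 mm and lost below. Likewise `examples/xray_wire_resolution.py` images a
0.4-mm absorbing wire and reports the Gaussian-fit full width at half
maximum of its profile (`FWHM = 1.17 mm` — the low-pass acquisition kernel,
not the wire, sets this), and `examples/fluorescence_sensitivity.py` fits a
calibration line through ROI means of a two-fold dilution series
(`slope 0.973, R^2 = 0.9999, detection limit 0.74 nmol/ml`).

The same experiments are available from the shell:

```sh
fsikit preset wire --out runs/wire --seed 1
fsikit reconstruct runs/wire/measurements.csv --out runs/wire-replay
```

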