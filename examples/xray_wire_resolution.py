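"""X-ray resolution experiment: image a 0.4-mm wire, fit its profile.

The virtual instrument renders an absorbing metal wire on a bright
transmission field, acquires it at 14% circular sampling with dithered
patterns, reconstructs, and fits a Gaussian to a profile drawn across the
wire.  The fit's full width at half maximum (in mm, via the 0.52 mm pixel
pitch) is the standard single-number summary of spatial resolution.
"""

from fsikit.workbench import run_experiment, wire_preset

result = run_experiment(wire_preset(seed=1))
r = result.report
print(f"scene: 0.4-mm wire, {result.scene.shape[0]}x{result.scene.shape[1]} px, "
      f"pitch {result.scene.pitch_mm} mm; plan: {len(result.plan)} coefficients "
      f"({result.plan.coverage:.1%} coverage)")
print(f"Gaussian fit of the wire profile: center {r['center_px']:.2f} px, "
      f"sigma {r['sigma_px']:.2f} px, amplitude {r['amplitude']:.3f} "
      "(negative: an absorption dip)")
print(f"FWHM = {r['fwhm_mm']:.2f} mm")
print("The FWHM exceeds the 0.4-mm wire because the 14% low-pass acquisition "
      "sets the resolution; it is the imaging kernel we measure, not the wire.")
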