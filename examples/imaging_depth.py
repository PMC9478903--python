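"""Imaging depth: a fluorescent tube buried in a scattering medium.

A 1-mm tube is placed at 2, 4, 6 and 8 mm depth in a medium with
mu_a = 0.03 /cm and mu_s' = 12.3 /cm; emission reaching the surface decays
as exp(-mu_eff * d) with mu_eff = sqrt(3 mu_a (mu_a + mu_s')) ~ 1.05 /cm
and spreads laterally with depth.  Detectability is judged by the
contrast-to-noise ratio against the Rose criterion (CNR >= 5).
"""

from fsikit.instrument import effective_attenuation
from fsikit.workbench import depth_series

print(f"mu_eff = {effective_attenuation(0.03, 12.3):.3f} /cm")
print(f"{'depth [mm]':>10} {'CNR':>8} {'detectable':>11}")
for rep in depth_series(seed=1):
    print(f"{rep['depth_mm']:>10.0f} {rep['contrast']:>8.2f} "
          f"{str(rep['detectable']):>11}")
print("The tube stays detectable to 4 mm; at 6-8 mm attenuation and "
      "diffusive blur push the CNR below the Rose threshold.")
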