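"""Build the phase-shifted fringe patterns and a circular sampling plan.

Each Fourier coefficient of the scene is probed by three sinusoidal
patterns with initial phases 0, 2*pi/3 and 4*pi/3; for a binary micromirror
modulator the grayscale fringes are Floyd-Steinberg dithered.  The circular
plan acquires the lowest radial frequencies first until 14% of the spectrum
(conjugates included) is covered.
"""

import numpy as np

from fsikit import circular_sampling_plan, triplet_for

shape = (96, 128)

triplet = triplet_for(3, 5, shape)
print(f"pattern triplet for (u, v) = (3, 5) on {shape[0]}x{shape[1]}:")
for k, phase in enumerate(("0", "2pi/3", "4pi/3")):
    g, b = triplet.grayscale[k], triplet.binary[k]
    print(f"  phase {phase:>5}: grayscale mean {g.mean():.4f}, "
          f"dithered mean {b.mean():.4f} (dither preserves the local mean)")
print(f"  pointwise sum of the three grayscale patterns: "
      f"{triplet.grayscale.sum(axis=0).min():.6f}..{triplet.grayscale.sum(axis=0).max():.6f}"
      " (three cosines 120 degrees apart cancel to 3/2)")

plan = circular_sampling_plan(shape, 0.14)
radii = [np.hypot(min(u, 96 - u), min(v, 128 - v)) for u, v in plan.coords]
print(f"\ncircular plan at 14%: {len(plan)} coefficients to display "
      f"({3 * len(plan)} patterns), covering {plan.coverage:.2%} of the "
      f"{96 * 128} spectrum bins with conjugates implied")
print(f"max radial frequency acquired: {max(radii):.1f} cycles "
      "(a low-pass disc in the Fourier plane)")
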