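"""Render each of the 16 localization patterns and check where the signal lands.

Builds one budded cell geometry, renders every class's GFP pattern into
it, and prints the fraction of fluorescence mass that falls inside the
class-defining region (nuclear disc, boundary ring, vacuole, ...).  A
fraction near 1 means the pattern is where the class says it should be.
"""

import numpy as np

from ensloc import phantom as P

geom = P.sample_geometry(np.random.default_rng(3), budded=True, center=(32.0, 32.0))
shape = (64, 64)

print(f"{'class':<28}{'mass in region':>15}{'image mass':>12}")
for label in P.CLASSES:
    img = P.render_pattern(label, geom, expression=100.0, seed=11, shape=shape)
    region = P.class_region_mask(label, geom, shape)
    frac = img[region].sum() / img.sum()
    print(f"{label:<28}{frac:>15.3f}{img.sum():>12.0f}")

print(
    "\nEach row is one localization class rendered into the same cell; the"
    "\nmass fraction shows how tightly the pattern is confined to its"
    "\ndefining region (>= 0.85 by construction)."
)
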