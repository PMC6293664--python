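"""Evaluate the four collective-level trait maps on one 32-cell collective.

Volume reads the cell phenotype as a volume and sums it; the other three
read it as a radius.  Swim speed declines with cell radius (heavier cells,
same thrust), survival rises with collective radius (escape from
gape-limited predators).
"""

import numpy as np

from heritsim import TRAIT_MAPS

rng = np.random.default_rng(3)
cells = rng.normal(1.5, 0.25, size=32)  # one collective's cell phenotypes

for name, trait in TRAIT_MAPS.items():
    print(f"{name:>9}: {trait(cells):12.6g}")

# Volume ~ 32 * 1.5 = 48; diameter is that of the sphere formed by 32
# spherical cells of radius ~1.5; swim speed is negative at these radii
# (the collective sinks); survival is tiny because 0.5 * r * sqrt(32) ~ 4.2
# is far below the logistic midpoint at 25 - a collective this small is
# well inside the predation window.
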