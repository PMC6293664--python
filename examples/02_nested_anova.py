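"""Nested-ANOVA heritability on a table with known variance components.

A balanced table (10 clones x 8 collectives x 32 particles) is simulated
with among-clone variance 1.0, among-collective variance 0.25 and
within-collective variance 1.0.  The sums of squares partition total
phenotypic variation; particle-level heritability is SSA / SST, the
collective trait is the within-collective mean, and the ratio of
collective- to particle-level heritability follows the closed formula
(SSA + SS(B/A) + SS(C/B)) / (SSA + SS(B/A)) >= 1.
"""

import numpy as np

from heritsim import (
    collective_H2, collective_ss, heritability_ratio, nested_ss,
    particle_H2, simulate_nested_table,
)

rng = np.random.default_rng(11)
table = simulate_nested_table(a=10, b=8, c=32,
                              var_a=1.0, var_b=0.25, var_c=1.0,
                              mean=1.5, rng=rng)
ss = nested_ss(table)
zss = collective_ss(table.collective_means())

print(f"SSA (among clones):               {ss.ssa:10.2f}")
print(f"SS(B/A) (collectives in clones):  {ss.ss_b_a:10.2f}")
print(f"SS(C/B) (particles in colls):     {ss.ss_c_b:10.2f}")
print(f"particle-level H2:                {particle_H2(ss).h2:10.3f}")
print(f"collective-level H2:              {collective_H2(zss).h2:10.3f}")
print(f"heritability ratio (>= 1):        {heritability_ratio(ss):10.3f}")
# With these components the expected particle H2 is roughly
# 1.0 / (1.0 + 0.25 + 1.0) ~ 0.44, while averaging 32 particles shrinks
# the within-collective term, lifting collective H2 toward
# 1.0 / (1.0 + 0.25 + 1.0/32) ~ 0.78.
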