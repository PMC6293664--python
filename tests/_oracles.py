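"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_ss(y: np.ndarray):
    """Triple-loop nested deviation sums, independent of the library path."""
    a, b, c = y.shape
    grand = y.mean()
    ssa = ss_ba = ss_cb = sst = 0.0
    for i in range(a):
        ssa += b * c * (y[i].mean() - grand) ** 2
        for j in range(b):
            ss_ba += c * (y[i, j].mean() - y[i].mean()) ** 2
            for k in range(c):
                ss_cb += (y[i, j, k] - y[i, j].mean()) ** 2
                sst += (y[i, j, k] - grand) ** 2
    return ssa, ss_ba, ss_cb, sst
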