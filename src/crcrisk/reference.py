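"""Published weight vectors for the 134-patient stage III CRC study cohort.

The original analysis reported one hazard-ratio-maximizing weight vector per
OS-sorted training fold (W1..W5) over the proteins (Bak, Bax, Bcl2, BclXL,
Mcl1), and their componentwise average W*.  They are kept here so the
pipeline can be run in *injection mode* — scoring a cohort with the published
weights instead of re-running the search — and as inputs to cross-checks.
"""

import numpy as np

from .cohort import PROTEINS  # noqa: F401  (column order of the weights)

#: W1..W5, rows in fold order, columns (bak, bax, bcl2, bclxl, mcl1)
REPORTED_FOLD_WEIGHTS = np.array([
    [0.0, 0.2, -0.1, -0.8, -0.9],
    [0.0, 0.1, -0.1, -0.9, -0.3],
    [0.0, 0.2,  0.0, -0.9,  0.0],
    [0.0, 0.2, -0.2, -0.9, -0.8],
    [0.1, 0.0, -0.1, -0.7, -0.7],
])

#: componentwise average of the five fold weights, as published (2 decimals)
REPORTED_W_STAR = np.array([0.02, 0.14, -0.1, -0.84, -0.54])

#: published clinical-feature weights of the hybrid combinations; numeric
#: features map to a scalar, categorical features to a weight per level
REPORTED_HYBRID_WEIGHTS = {
    "age": -0.2,
    "gender": {"male": 0.1, "female": -1.0},
    "lvi": {"yes": -1.0, "no": 0.5},
    "t_stage": {"T2&3": -1.0, "T4": -0.2},
    "n_stage": {"N1": -1.0, "N2": -0.3},
}
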