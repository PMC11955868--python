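"""Reference area/overlap matrices for the porcine mid-cervical vagus nerve.

These are the reported region area fractions (diagonal) and pairwise
shared-area fractions (off-diagonal) of the laryngeal (L), pulmonary (P),
cardiac-efferent (CE) and cardiac-afferent (CA) regions, per technique:
microCT fascicle tracing (n = 5 nerves) and spatially selective stimulation
(sVNS, n = 10 animals), plus the between-technique shared fraction per
region. They serve as replay inputs for the relative-overlap computation
and as worked-example fixtures; they are measured values, not outputs of
this package.
"""

from __future__ import annotations

import numpy as np

from .stats import OverlapMatrix

# Rows/columns ordered L, P, CE, CA.
MICROCT_MATRIX = OverlapMatrix(
    technique="microct",
    matrix=np.array(
        [
            [0.74, 0.42, 0.23, 0.24],
            [0.42, 0.65, 0.07, 0.31],
            [0.23, 0.07, 0.23, 0.00],
            [0.24, 0.31, 0.00, 0.34],
        ]
    ),
)

SVNS_MATRIX = OverlapMatrix(
    technique="svns",
    matrix=np.array(
        [
            [0.43, 0.40, 0.32, 0.40],
            [0.40, 0.61, 0.32, 0.59],
            [0.32, 0.32, 0.40, 0.33],
            [0.40, 0.59, 0.33, 0.75],
        ]
    ),
)

# Shared-area fraction of each region between the two techniques.
BETWEEN_TECHNIQUES = {
    "laryngeal": 0.40,
    "pulmonary": 0.50,
    "cardiac_efferent": 0.22,
    "cardiac_afferent": 0.33,
}
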