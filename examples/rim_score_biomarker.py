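"""Rim-PDL1 score on a synthetic immuno-architecture phantom.

Builds a label volume with a PDL1+ cuff enveloping a PDL1- core (the
pattern high-burden/high-strength tumours develop), takes the three central
cross sections, computes Euclidean distance-to-surface maps, and scores the
fraction of PDL1+ cancer cells within rims of increasing depth.
"""

import numpy as np

from tmesim import score_snapshot
from tmesim.config import CANCER_PDL1_NEG, CANCER_PDL1_POS

n = 60
labels = np.zeros((n, n, n), np.uint8)
labels[15:45, 15:45, 15:45] = CANCER_PDL1_NEG       # 300 um tumour cube
shell = np.zeros_like(labels, bool)
shell[15:45, 15:45, 15:45] = True
core = np.zeros_like(labels, bool)
core[19:41, 19:41, 19:41] = True
labels[shell & ~core] = CANCER_PDL1_POS             # ~40 um PDL1+ cuff

print("rim depth (um)   PDL1+ fraction in rim")
for thr in (20.0, 50.0, 100.0, 150.0):
    score = score_snapshot(labels, threshold_um=thr)
    print(f"{thr:13.0f}   {score.score:.3f}")

print(
    "\nThin rims isolate the PDL1+ cuff (score near 1); deep rims dilute it "
    "with the PDL1- core, which is why thin-rim scores separate responders "
    "from non-responders better in the virtual cohort."
)
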