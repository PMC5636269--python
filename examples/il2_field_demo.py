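"""IL-2 diffusion/decay on the lattice with the averaged two-sweep ADE solver.

Places a cluster of secreting cells, advances the field, and prints total
mass against the analytic sources-minus-decay balance plus the spread of the
concentration profile.
"""

import numpy as np

from tmesim import CytokineField
from tmesim.config import CytokineParameters

# the effective slow-diffusion parameterization used in scenario runs:
# niche length sqrt(D/k) ~ 25 um, the range over which IL-2 gates division
params = CytokineParameters(diffusion_um2_s=0.1, decay_rate_h=0.693,
                            secretion_rate_h=1.0, substeps_per_dt=1)
field = CytokineField.zeros(40, params, dx_um=10.0, dt_abm_h=0.25)

sources = np.array([[20, 20, 20], [21, 20, 20], [20, 21, 20]])
print("hour   total mass   peak concentration")
for step in range(48):  # 12 hours
    field.add_sources(sources, 0.25)
    field.step(0.25)
    if (step + 1) % 8 == 0:
        print(f"{(step + 1) * 0.25:4.0f}   {field.total_mass():10.4f}"
              f"   {field.grid.max():12.5f}")

k = params.decay_rate_h
steady = len(sources) * params.secretion_rate_h / k
print(f"\nanalytic steady-state mass S/k = {steady:.4f}")
print(
    "Total mass approaches the secretion/decay balance while the profile "
    "stays localized: the ~25 um niche sqrt(D/k) that gates T-cell division."
)
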