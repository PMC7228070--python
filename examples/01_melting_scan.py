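"""Free-energy profile of global unwinding and the melting onset.

Scans supercoiling density for the two packaged 50-bp duplexes and
reports where denaturation starts to dominate the ensemble.
"""

import numpy as np

from torsionmelt import free_energy_profile, reference_sequences, reference_parameters, transition_sigma

grid = np.arange(0.0, 0.1201, 0.002)
for label, seq in reference_sequences().items():
    params = reference_parameters(label)
    prof = free_energy_profile(seq, grid, params)
    onset = transition_sigma(seq, params)
    i = np.searchsorted(grid, onset)
    print(f"{label}: melting onset sigma = {onset:.3f}; "
          f"F at onset = {prof.free_energy[i]:.2f} kcal/mol; "
          f"F at sigma=0.12 = {prof.free_energy[-1]:.2f} kcal/mol")

print("\nThe free energy rises quadratically while the duplex stays intact, "
      "then flattens once a soft denaturation bubble absorbs further untwist.")
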