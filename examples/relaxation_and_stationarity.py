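"""Spectral analysis of a microstate rate matrix.

Loads the packaged four-state (ALA5) and seven-state (ALA8) reference
rate matrices, and prints their stationary populations and relaxation
times. The slowest relaxation is the global folding/unfolding time of
the peptide; the stationary coil population shows how strongly the
short helices are destabilised.
"""

import numpy as np

from hbfold import fixtures, relaxation_times, stationary_distribution

fx = fixtures()
for name, K in [("ALA5 (4 states)", fx.ala5_rates), ("ALA8 (7 states)", fx.ala8_rates)]:
    p = stationary_distribution(K)
    taus = relaxation_times(K)
    print(name)
    print("  stationary populations:", np.round(p.p, 4))
    print(f"  slowest relaxation: {taus[0]:.2f} ns (full spectrum: "
          f"{np.round(taus, 2)} ns)")
print("The coil state dominates both ensembles; folding relaxation slows "
      "roughly tenfold from the 4-state to the 7-state peptide.")
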