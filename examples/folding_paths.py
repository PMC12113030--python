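"""Widest (maximum-bottleneck) folding paths on the flux network.

Edge weights are the detailed-balance-symmetrised reactive fluxes
F_ij = (k_ij p_j + k_ji p_i)/2; the global maximum weight path is the
folding route whose rate-limiting (bottleneck) edge carries the most
flux, with every sub-path itself optimal.
"""

from hbfold import fixtures, flux_weights, gmwp, stationary_distribution

fx = fixtures()
for name, K in [("ALA5", fx.ala5_rates), ("ALA8", fx.ala8_rates)]:
    p = stationary_distribution(K)
    net = flux_weights(K, p)
    res = gmwp(net, 0, K.n_states - 1)
    print(f"{name}: GMWP {' -> '.join(map(str, res.path))}, "
          f"bottleneck edge {res.bottleneck_edge} "
          f"(flux {res.bottleneck_weight:.3f} p·μs⁻¹)")
print("The 4-state peptide folds directly coil -> helix; the 7-state one "
      "passes through a single intermediate with 4 hydrogen bonds, and its "
      "bottleneck is the initial 0 -> 4 nucleation step.")
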