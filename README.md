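# hbfold

Helix–coil folding kinetics of alanine peptides analysed through a single
discrete reaction coordinate: **NHB**, the number of formed α-helical
i → i+4 hydrogen bonds.

`hbfold` is for people who study peptide folding with molecular dynamics
and want the one-dimensional hydrogen-bond picture of it: instead of
clustering 3D structures, every frame is reduced to a (weighted) count of
its helical hydrogen bonds, and folding becomes hopping between the
MAXHB + 1 integer microstates NHB = 0 … MAXHB (MAXHB = n − 2 for a blocked
(ALA)n). On that small state space the package provides the full kinetic
tool chain:

- **Coordinate** — per-bond O…N distances → cubic-ramp bond weights
  (1 below 3.2 Å, 0 above 4.0 Å, Hermite smoothstep between) → NHB(t) →
  integer microstates; helix fraction f = ⟨NHB⟩/MAXHB.
- **Microstate kinetics** — moving-window transition counts at lag τ,
  column-stochastic T, generator K = log(T)/τ (μs⁻¹, K[i,j] = rate j→i,
  columns sum to zero), stationary distribution, relaxation times
  τ_m = −1/λ_m, implied-timescale scans, and delta-method standard errors.
- **Folding paths** — flux networks with symmetrised edge weights
  F_ij = (k_ij p_j + k_ji p_i)/2 and the global maximum weight path
  (recursive widest-path search: maximal bottleneck, every sub-path
  optimal).
- **Coarse graining** — PCCA+ metastable partitions and small (N = 2–4)
  coarse rate matrices fitted by propagator matching, with coil /
  intermediate / helix labels and two-state summaries
  (τ_u, τ_f, ΔG = −RT ln Π_h/Π_c).
- **Committors** — transition-path-theory committors q on the generator,
  transition states at q ≈ 1/2.
- **Boundary diffusion** — Bicout–Szabo-style position-dependent diffusion
  D = a²√(k₊k₋) per hydrogen-bond step (a = 1.5 Å helical rise) and
  friction f = k_BT/D.
- **Patterns** — 0/1 bond-pattern population tables and the combinatorics
  C(n, k) of partial helices, flagging terminal-contiguous runs.
- **Synthetic data** — exact-event CTMC simulation from any generator and
  distance tables that realise a prescribed microstate sequence, so the
  entire chain is testable without MD trajectories. Reference four-state
  (ALA5) and seven-state (ALA8) rate matrices and the ALA5 pattern table
  ship as fixtures.

## Worked example

```python
import numpy as np
from hbfold import (fixtures, relaxation_times, stationary_distribution,
                    flux_weights, gmwp, diffusion_profile)

K = fixtures().ala8_rates                      # 7-state reference generator, μs⁻¹
p = stationary_distribution(K)
print(np.round(p.p, 3))                    # [0.784 0.061 0.035 0.031 0.028 0.026 0.036]
print(relaxation_times(K)[0])              # 32.70 ns — global folding relaxation

net = flux_weights(K, p)
print(gmwp(net, 0, 6).path)                # (0, 4, 6): coil -> 4-bond intermediate -> helix

prof = diffusion_profile(K)                # a = 1.5 Å, T = 300 K
print(round(prof.D_avg / 1e-15))           # 450 (x1e-15 m²/s boundary diffusion)
```

The slowest relaxation (32.7 ns) is the folding/unfolding time of the
6-bond helix; the widest folding path shows nucleation straight into a
4-bond intermediate followed by helix completion; the average boundary
diffusion coefficient of 450×10⁻¹⁵ m² s⁻¹ quantifies how fast the
helix–coil boundary migrates per residue step.

Each capability also has a short narrative script under `examples/`
(`python examples/folding_paths.py`, …), and a thin CLI mirrors the
library for TSV-file workflows:

```bash
hbfold simulate --generator ala5 --duration-us 5 --dt-ps 20 --out states.tsv
hbfold kinetics states.tsv --dt-ns 0.02 --lag-ns 2 --n-residues 5 --out K.tsv
hbfold gmwp ala8
```

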