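# Methods

This note records the models, estimators and numerical choices behind
`hbfold`, and what the synthetic-data tests do and do not demonstrate.

## The hydrogen-bond-count coordinate

A blocked (ALA)n peptide supports MAXHB = n − 2 candidate α-helical
i → i+4 hydrogen bonds, from the acetyl C=O → HN(residue 4) to the
residue (n − 3) C=O → C-terminal amide. Each bond's O…N distance d maps
to a weight w(d): 1 for d ≤ 3.2 Å, 0 for d ≥ 4.0 Å, and the Hermite
smoothstep

    w(d) = 1 − 3t² + 2t³,  t = (d − 3.2)/0.8

in between. The smoothstep is our choice of cubic: it is the unique
cubic that is C¹ at both cutoffs (zero slope at 3.2 and 4.0 Å), is
monotone, and passes through 1/2 at 3.6 Å. Frame weights sum to the
continuous coordinate NHB(t) ∈ [0, MAXHB]; microstates are the nearest
integers, with half-integer ties rounded up (deterministic; affects a
negligible fraction of frames for realistic distance distributions).
Distances are taken as given — no periodic-boundary imaging or geometry
is computed here.

## Rate-matrix estimation

Transitions are counted with a moving window of length τ (the lag)
sliding one frame at a time; independent trajectories pool counts and
windows never straddle a trajectory boundary. Columns of the count
matrix are normalised into a column-stochastic T(τ), and the generator
is estimated as the principal matrix logarithm K = log T/τ, projected
onto the set of valid generators (negative off-diagonal elements — which
appear only at noise level — clipped to zero, diagonals reset to minus
the column sum). When the logarithm has non-real branches (possible for
strongly non-Markovian or degenerate inputs) the first-order estimate
(T − I)/τ is used instead with a warning. Rates are reported in μs⁻¹
with the convention K[i, j] = rate j → i and zero column sums; raw
counts are used for estimation, with symmetrisation (C + Cᵀ)/2 reserved
for flux edge weights where detailed balance is wanted by construction.

Standard errors: each column of T carries multinomial noise with an
effective sample size discounted by dt/τ (windows one frame apart are
almost completely overlapping), plus a one-pseudocount floor so that
unobserved transitions keep finite error bars. This noise is pushed
through the matrix logarithm with a numerically differenced Fréchet
derivative — essential when fast relaxation modes are comparable to the
lag, where element-wise binomial errors underestimate the true spread
by factors of 2–3. Against 20 independent simulations of the four-state
reference system the delta-method errors match the empirical scatter to
within ~25% per element.

Stationary distributions are the eigenvector of the smallest-magnitude
eigenvalue rather than an exact null-space: matrices transcribed at
printed precision have column-sum residuals of ±0.1 μs⁻¹, which shifts
the zero mode to ~10⁻⁴ of the leading rates. `relaxation_times`
correspondingly drops the single eigenvalue closest to zero and returns
τ_m = −1/λ_m for the rest, slowest first.

## Relaxation analysis and the two-state model

Autocorrelation functions use the biased (divide-by-N), mean-subtracted
FFT estimator; the biased form has smoother tails, which matters for
exponential fitting. Two-exponential fits a₁e^{−t/τ₁} + a₂e^{−t/τ₂} are
deterministic bounded least squares: amplitudes in [0, 1.5], times in
[dt/10, 10 t_max], initialised from the first 1/e crossing (τ₁ =
crossing/5, τ₂ = 5×crossing), no random restarts. Fits whose time
scales collapse (ratio < 1.2) or whose fast amplitude vanishes are
flagged degenerate rather than rejected. The two-state model converts a
helix fraction f and slow time τ₂ into K = f/(1 − f), k_u =
1/τ₂ · 1/(1 + K), k_f = 1/τ₂ · K/(1 + K) (so k_u + k_f = 1/τ₂ is an
identity) and ΔG = −RT ln K with R = 0.0019872 kcal mol⁻¹ K⁻¹.
Temperatures are explicit everywhere: kinetics and ΔG default to the
300 K simulation temperature, free-energy *profiles* of populations
(−RT ln p_i/p_max) default to 298 K, matching the convention the
reference landscapes were drawn at.

## Widest folding paths

The kinetic network is undirected with symmetrised reactive-flux
weights F_ij = (k_ij p_j + k_ji p_i)/2 (zero-weight edges omitted;
zero-population nodes excluded with a warning). The maximum-bottleneck
(widest) path is found by descending-weight union-find for the
bottleneck value, then a fewest-hops, lexicographically-smallest path
restricted to edges at or above it — making tie-breaking fully
deterministic. The *global* maximum weight path is built recursively:
pin the bottleneck edge (u, v) of the widest s–t path, refine (s, u)
and (v, t) recursively with each half forbidden from re-using nodes
committed to the other, and concatenate. If exclusions disconnect a
half, the plain widest sub-path is kept. On random graphs of up to 8
nodes the result matches exhaustive enumeration, and every contiguous
sub-path audits as a widest path between its endpoints; the node
sequence is invariant under any strictly increasing transformation of
the weights.

## Coarse graining

PCCA+ partitions come from the inner-simplex construction on the N
dominant right eigenvectors of the (row-stochastic) transition matrix:
greedily select the N most spread-out eigenvector rows as simplex
vertices, transform onto that simplex, assign each microstate to its
maximum-membership aggregate. Eigenvalue degeneracy at the spectral cut
is an error (choose a different N). Aggregates are not forced to be
contiguous in NHB, though in practice they are.

The coarse rate matrix R minimises

    Σ_{m=1..5} ‖ A e^{Kmτ} diag(p) Aᵀ − e^{Rmτ} diag(Π) ‖²

over valid N-state generators, where A is the aggregation indicator,
p the fine stationary distribution and Π = A p. R is parameterised by
the logs of its off-diagonal rates (positivity and zero column sums by
construction) with a quadratic penalty keeping Π stationary under R;
optimisation is deterministic Nelder–Mead from the locally aggregated
generator R₀[I,J] = Σ_{i∈I,j∈J} K[i,j] p_j / Π_J, which is exactly
Π-stationary and, for lumpable K, already the exact optimum (the fit
then returns it unchanged, and with the identity partition it returns K
itself). Five lag multiples balance resolving the slow mode against
conditioning; the fitted two-state models of the four-state reference
system land within a few percent of its reference coarse
rates, and coarse slowest relaxations stay within 30% of the fine ones.
Labels: the aggregate containing NHB = 0 is the coil, the one
containing MAXHB the helix, the rest intermediates; τ_f and τ_u of a
two-state model are the inverses of the corresponding off-diagonal
rates of R.

## Committors and transition states

Committors solve Σ_j k(i→j)(q_j − q_i) = 0 on the continuous-time
generator with q = 0 on the coil set and q = 1 on the helix set, as one
linear system. Working on the generator makes q lag-independent; a
discrete-time variant (rates replaced by T − I) is available for
cross-checks against lagged-transition-matrix tools. Transition states
are all states with |q − 1/2| ≤ band (default 0.1), always including
the single closest state. For the seven-state reference system the
generator-level committor places the transition region at 4–5 bonds
(q(4) ≈ 0.45, q(5) ≈ 0.60); both candidates are reported since the
crossing sits between them.

## Boundary diffusion

One hydrogen bond gained moves the helix–coil boundary by one step
a (default 1.5 Å, the α-helical rise per residue). Nearest-neighbour
hopping then maps onto discretised 1D diffusion with the geometric-mean
form D_{i,i+1} = a²√(k(i→i+1)·k(i+1→i)) — the discretised-Smoluchowski
choice consistent with detailed balance — and friction k_BT/D per edge
(an exact identity, tested as such). Averages are arithmetic means over
edges; the quoted spread is the sample standard deviation of the
per-edge values, i.e. genuine position-dependence, not a statistical
error bar. Edges with a vanishing rate are excluded with a warning.
This form reproduces the reference averages of both
reference systems (1600 and 450 ×10⁻¹⁵ m² s⁻¹).

## Pattern statistics

Patterns collapse the per-bond weights at a threshold of 0.5 — the
midpoint of the cubic ramp — to 0/1 strings; populations are tabulated
per NHB class, whose sums reproduce the microstate populations of the
same frames exactly. C(n, k) counts the possible arrangements of k
formed bonds. The terminal-helix report flags patterns whose formed
bonds form a single run touching the N- or C-terminus, the
configurations observed to be anomalously stable.

## Synthetic data: what it shows and what it does not

The generator layer emulates exactly what the analysis consumes:
continuous-time Markov jump dynamics in microstate space (exact-event
Gillespie simulation, exponential waiting times, sampled on a regular
frame grid) and distance tables whose weights reproduce a prescribed
state sequence (formed bonds uniform in [2.8, 3.15] Å, broken in
[4.1, 5.5] Å, formed positions following terminal-contiguous runs with
a 15% scattered admixture). Seeds are threaded through a documented
two-stream scheme — placement and distance noise are separate streams —
so runs are bit-reproducible and distance noise never perturbs states.

Passing the recovery tests therefore shows that the estimators are
correct *for Markovian dynamics in NHB space*. Real MD trajectories are
only approximately Markovian at finite lag, distances are correlated in
time, and bond patterns have richer structure than the terminal-run
rule; none of these effects are emulated, and agreement on synthetic
data does not certify behaviour under them. Test problem sizes — 3 × 5 μs
at 1 ps framing for rate recovery, 10⁴ shooting trials per state for
Monte-Carlo committors, graphs of ≤ 8 nodes for exhaustive path
enumeration — are the package's validation conditions, chosen so that
expected statistical deviations sit well inside the 3-standard-error
acceptance bands.

## Known limitations

- No reversible maximum-likelihood estimation with detailed-balance
  constraints, and no Bayesian error models; symmetrisation is the only
  reversibility device, applied to flux weights.
- Only i → i+4 α-helical bonds; no 3₁₀/π variants, no DSSP.
- The widest-path machinery is undirected; directed flux decompositions
  are out of scope.
- Coarse models are crisp; no fuzzy memberships.
- The (T − I)/τ fallback biases rates low when triggered; it exists for
  degenerate inputs and is always accompanied by a warning.
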