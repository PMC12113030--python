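"""Metastable coarse graining: PCCA+ partitions and coarse rate models.

PCCA+ groups microstates into N metastable aggregates from the simplex
structure of the N dominant eigenvectors of the transition matrix.
On top of a crisp partition, a coarse N x N rate matrix R is fitted so
that its propagator best matches the aggregated fine-grained propagator
over several lag multiples while exactly preserving the aggregated
stationary distribution (the optimal-dimensionality-reduction idea).
Aggregates are labelled coil (contains NHB = 0), helix (contains
NHB = MAXHB) and intermediate (the rest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .kinetics import (
    RateMatrix,
    StationaryDistribution,
    TransitionMatrix,
    relaxation_times,
    stationary_distribution,
)


class DegeneratePartitionError(ValueError):
    """Coil and helix anchor microstates fell in the same aggregate."""


@dataclass(frozen=True)
class Partition:
    """Crisp microstate -> aggregate assignment."""

    assignment: np.ndarray  # aggregate index per microstate
    n_aggregates: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        present = set(a.tolist())
        if present != set(range(self.n_aggregates)):
            raise ValueError("every aggregate must be non-empty")
        object.__setattr__(self, "assignment", a)

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == j)

    def indicator(self) -> np.ndarray:
        """Aggregation map A, shape (N, n_micro): A[J, i] = 1 if i in J."""
        A = np.zeros((self.n_aggregates, len(self.assignment)))
        A[self.assignment, np.arange(len(self.assignment))] = 1.0
        return A


@dataclass(frozen=True)
class CoarseModel:
    R: np.ndarray  # N x N generator, μs⁻¹, R[I, J] = rate J -> I
    Pi: np.ndarray  # aggregate populations
    labels: tuple[str, ...]  # 'coil' | 'helix' | 'intermediate'
    partition: Partition
    relaxations: np.ndarray  # ns, slowest first
    lag: float  # ns


@dataclass(frozen=True)
class TwoStateSummary:
    tau_u: float  # ns
    tau_f: float  # ns
    dG: float  # kcal/mol


def pcca_plus(t: TransitionMatrix, n: int) -> Partition:
    """Crisp PCCA+ partition into n metastable aggregates.

    Uses the inner-simplex algorithm on the n dominant right
    eigenvectors of the row-stochastic transition matrix: vertex states
    spanning the eigenvector simplex are located, memberships follow
    from the linear transform onto that simplex, and each microstate is
    assigned to its maximum-membership aggregate.
    """
    m = t.T.shape[0]
    if not 2 <= n <= m:
        raise ValueError(f"need 2 <= n <= {m} aggregates, got {n}")
    Trow = t.T.T  # row-stochastic convention for spectral analysis
    w, v = np.linalg.eig(Trow)
    order = np.argsort(-w.real)
    w = w.real[order]
    if n < m and abs(w[n - 1] - w[n]) < 1e-12:
        raise ValueError(
            f"eigenvalue degeneracy at the spectral cut (λ_{n} = λ_{n + 1}); "
            "try a different number of aggregates"
        )
    psi = v[:, order[:n]].real
    psi[:, 0] = 1.0  # stationary eigenvector is constant up to scaling
    # inner simplex: greedily pick the n most spread-out rows as vertices
    vertices = [int(np.argmax(np.linalg.norm(psi, axis=1)))]
    basis = psi - psi[vertices[0]]
    for _ in range(1, n):
        norms = np.linalg.norm(basis, axis=1)
        nxt = int(np.argmax(norms))
        vertices.append(nxt)
        b = basis[nxt] / norms[nxt]
        basis = basis - np.outer(basis @ b, b)
    chi = psi @ np.linalg.inv(psi[vertices])
    raw = np.argmax(chi, axis=1)
    # relabel aggregates by their smallest member for determinism
    firsts = sorted(range(n), key=lambda j: int(np.min(np.flatnonzero(raw == j))))
    relabel = {old: new for new, old in enumerate(firsts)}
    assignment = np.array([relabel[a] for a in raw])
    return Partition(assignment=assignment, n_aggregates=n)


def aggregate_populations(part: Partition, p: StationaryDistribution) -> np.ndarray:
    return part.indicator() @ p.p


def _lumped_generator(K: np.ndarray, p: np.ndarray, part: Partition) -> np.ndarray:
    """Locally aggregated generator: population-weighted rate averages.

    R[I, J] = Σ_{i∈I, j∈J} K[i, j] p_j / Π_J — exact when K is lumpable
    with respect to the partition; otherwise the fit initialisation.
    """
    A = part.indicator()
    Pi = A @ p
    R = A @ (K * p[None, :]) @ A.T / Pi[None, :]
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=0))
    return R


def _generator_from_offdiag(rates: np.ndarray, N: int) -> np.ndarray:
    """Generator from its N(N-1) off-diagonal rates (column-major order)."""
    R = np.zeros((N, N))
    off = ~np.eye(N, dtype=bool)
    R[off] = rates
    np.fill_diagonal(R, -R.sum(axis=0))
    return R


def odr_fit(
    k: RateMatrix,
    part: Partition,
    lag: float,
    maxhb: int | None = None,
    n_lag_multiples: int = 5,
) -> CoarseModel:
    """Coarse rate matrix by propagator matching.

    Minimises Σ_{m=1..M} ‖A exp(K m τ) diag(p) Aᵀ − exp(R m τ) diag(Π)‖²
    over N-state generators R, where A is the aggregation indicator map,
    p the fine stationary distribution and Π = A p its aggregation. R is
    parameterised through the logs of its off-diagonal rates (keeping it
    a valid generator by construction); a quadratic penalty keeps Π
    stationary under R. Optimisation is deterministic local descent from
    the locally aggregated generator, which is exactly Π-stationary and,
    for lumpable K, already the exact optimum.
    """
    K = k.K
    p = stationary_distribution(k).p
    A = part.indicator()
    N = part.n_aggregates
    Pi = A @ p
    tau_ns = lag
    Kns = K / 1e3  # μs⁻¹ -> ns⁻¹ for exp(K τ) with τ in ns
    # aggregated fine propagator correlation matrices
    targets = [
        A @ scipy.linalg.expm(Kns * (m * tau_ns)) @ np.diag(p) @ A.T
        for m in range(1, n_lag_multiples + 1)
    ]

    def objective(logr):
        R = _generator_from_offdiag(np.exp(logr), N)
        err = 0.0
        for m, tgt in enumerate(targets, start=1):
            P = scipy.linalg.expm((R / 1e3) * (m * tau_ns)) @ np.diag(Pi)
            err += np.sum((P - tgt) ** 2)
        # stationarity of Pi under R, nondimensionalised by the lag
        err += 1e4 * np.sum((R @ Pi * tau_ns / 1e3) ** 2)
        return err

    R0 = _lumped_generator(K, p, part)
    off = ~np.eye(N, dtype=bool)
    x0 = np.log(np.clip(R0[off], 1e-12, None))
    res = scipy.optimize.minimize(objective, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-14,
                                           "maxiter": 50000, "maxfev": 50000})
    if not (res.success or res.fun <= objective(x0) + 1e-15):
        raise RuntimeError(
            f"coarse rate fit failed: {res.message}; objective {res.fun}"
        )
    best = res.x if res.fun <= objective(x0) else x0
    R = _generator_from_offdiag(np.exp(best), N)
    m = maxhb if maxhb is not None else K.shape[0] - 1
    labels = classify_aggregates(part, m)
    return CoarseModel(
        R=R, Pi=Pi, labels=labels, partition=part,
        relaxations=relaxation_times(RateMatrix(K=R)), lag=lag,
    )


def classify_aggregates(part: Partition, maxhb: int) -> tuple[str, ...]:
    """coil = aggregate of NHB 0; helix = aggregate of NHB maxhb."""
    coil = int(part.assignment[0])
    helix = int(part.assignment[maxhb])
    if coil == helix:
        raise DegeneratePartitionError(
            "coil (NHB=0) and helix (NHB=maxhb) microstates fall in the "
            "same aggregate"
        )
    return tuple(
        "coil" if j == coil else "helix" if j == helix else "intermediate"
        for j in range(part.n_aggregates)
    )


def two_state_summary(
    model: CoarseModel, temperature: float = DEFAULT_TEMPERATURE
) -> TwoStateSummary:
    """Folding/unfolding times and ΔG of a two-aggregate model.

    τ_f = 1/R[helix <- coil], τ_u = 1/R[coil <- helix] (rates in μs⁻¹,
    times in ns), ΔG = -RT ln(Π_helix/Π_coil).
    """
    if model.partition.n_aggregates != 2:
        raise ValueError("two-state summary requires an N=2 model")
    helix = model.labels.index("helix")
    coil = model.labels.index("coil")
    tau_f = 1e3 / model.R[helix, coil]
    tau_u = 1e3 / model.R[coil, helix]
    dG = -R_KCAL * temperature * np.log(model.Pi[helix] / model.Pi[coil])
    return TwoStateSummary(tau_u=float(tau_u), tau_f=float(tau_f), dG=float(dG))
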