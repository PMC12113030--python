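"""Microstate kinetics: count, transition and rate matrices.

Transitions between NHB microstates are counted with a moving window of
length τ_lag sliding one frame at a time, as in Markov state modelling.
A column-stochastic transition matrix T (T[i, j] = P(state i at t+τ |
state j at t)) is obtained by column normalisation, and a rate matrix
(generator) K in μs⁻¹ by the principal matrix logarithm K = log(T)/τ,
projected onto the set of valid generators. Throughout the package
K[i, j] is the j -> i rate, columns of K sum to zero, and dp/dt = K·p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .hbonds import MicrostateTrajectory

NS_PER_US = 1e3  # ns per μs: converts 1/ns rates to μs⁻¹


class LagError(ValueError):
    """Lag incompatible with the trajectory time grid or span."""


class UnvisitedStateError(ValueError):
    """A microstate never occurs as a window source."""


class ReducibleGeneratorError(ValueError):
    """Generator does not connect all states."""


@dataclass(frozen=True)
class CountMatrix:
    """Moving-window transition counts; counts[i, j] = windows j -> i."""

    counts: np.ndarray
    lag: float  # ns
    n_windows: int
    dt: float | None = None  # frame interval of the counted trajectories, ns

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition probability matrix at a fixed lag."""

    T: np.ndarray
    lag: float  # ns

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if not np.allclose(T.sum(axis=0), 1.0, atol=1e-10):
            raise ValueError("columns of T must sum to 1")
        if T.min() < -1e-12 or T.max() > 1 + 1e-12:
            raise ValueError("transition probabilities must lie in [0, 1]")
        object.__setattr__(self, "T", T)


@dataclass(frozen=True)
class RateMatrix:
    """Continuous-time generator K, μs⁻¹; K[i, j] = rate j -> i."""

    K: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        off = K[~np.eye(K.shape[0], dtype=bool)]
        if off.size and off.min() < -1e-9:
            raise ValueError("off-diagonal rates must be non-negative")
        object.__setattr__(self, "K", K)

    @property
    def n_states(self) -> int:
        return self.K.shape[0]


@dataclass(frozen=True)
class StationaryDistribution:
    """Normalised stationary probabilities of a generator."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.min() < -1e-12:
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "p", np.clip(p, 0.0, None))


def count_transitions(
    traj: MicrostateTrajectory | list[MicrostateTrajectory],
    lag: float,
    n_states: int | None = None,
) -> CountMatrix:
    """Moving-window transition counts at lag ``lag`` (ns).

    Several independent trajectories pool their counts additively;
    windows never straddle a trajectory boundary.
    """
    trajs = traj if isinstance(traj, (list, tuple)) else [traj]
    if not trajs:
        raise ValueError("no trajectories given")
    dt = trajs[0].dt
    steps = lag / dt
    k = int(round(steps))
    if abs(steps - k) > 1e-9 or k < 1:
        raise LagError(f"lag {lag} ns is not a positive multiple of dt {dt} ns")
    m = n_states if n_states is not None else trajs[0].maxhb + 1
    counts = np.zeros((m, m))
    n_windows = 0
    for tr in trajs:
        if tr.dt != dt:
            raise LagError("all trajectories must share the same dt")
        s = tr.states
        if len(s) <= k:
            raise LagError(f"lag {lag} ns not shorter than trajectory span")
        src, dst = s[:-k], s[k:]
        np.add.at(counts, (dst, src), 1.0)
        n_windows += len(src)
    return CountMatrix(counts=counts, lag=lag, n_windows=n_windows, dt=dt)


def symmetrize_counts(c: CountMatrix) -> CountMatrix:
    """Detailed-balance symmetrisation C' = (C + Cᵀ)/2 (idempotent)."""
    return CountMatrix(
        counts=(c.counts + c.counts.T) / 2.0, lag=c.lag,
        n_windows=c.n_windows, dt=c.dt,
    )


def transition_matrix(c: CountMatrix) -> TransitionMatrix:
    """Column-normalise counts into transition probabilities."""
    col = c.counts.sum(axis=0)
    empty = np.flatnonzero(col == 0)
    if empty.size:
        raise UnvisitedStateError(
            f"state(s) {empty.tolist()} never occur as a window source"
        )
    return TransitionMatrix(T=c.counts / col, lag=c.lag)


def _project_to_generator(K: np.ndarray) -> np.ndarray:
    """Nearest valid generator: clip negative off-diagonals, fix diagonal."""
    K = K.copy()
    n = K.shape[0]
    off = ~np.eye(n, dtype=bool)
    K[off] = np.clip(K[off], 0.0, None)
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=0))
    return K


def rate_matrix_from_transition(t: TransitionMatrix) -> RateMatrix:
    """Generator estimate K = log(T)/τ in μs⁻¹.

    The principal matrix logarithm is projected to the nearest valid
    generator (negative off-diagonals clipped, diagonal reset to the
    negative column sum). If the logarithm comes out with substantial
    imaginary structure the first-order estimate (T - I)/τ is used
    instead, with a warning.
    """
    T = t.T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        L = scipy.linalg.logm(T)
    if np.max(np.abs(L.imag)) > 1e-6 * max(1.0, np.max(np.abs(L.real))):
        warnings.warn(
            "matrix logarithm has non-real branches; falling back to (T - I)/lag",
            RuntimeWarning,
            stacklevel=2,
        )
        L = T - np.eye(T.shape[0])
    K = _project_to_generator(L.real / t.lag) * NS_PER_US
    return RateMatrix(K=K)


def rate_standard_errors(c: CountMatrix) -> np.ndarray:
    """Approximate standard errors of the K = log(T)/τ estimates, μs⁻¹.

    Windows sliding by one frame overlap almost completely, so the
    effective number of independent windows sourced at state j is
    discounted by dt/lag: N_j = C_j · dt/lag. Each column of T carries
    multinomial sampling noise (with a pseudo-count floor so that
    unobserved transitions keep a finite error bar), which is propagated
    through the matrix logarithm by a numerically differentiated Fréchet
    derivative — the dominant effect when fast relaxation modes are
    comparable to the lag.
    """
    if c.dt is None:
        raise ValueError("count matrix lacks the frame interval dt")
    col = c.counts.sum(axis=0)
    if np.any(col == 0):
        raise UnvisitedStateError("unvisited source state; no error estimate")
    n = c.n_states
    T = c.counts / col
    n_eff = np.maximum(col * c.dt / c.lag, 1.0)
    L0 = scipy.linalg.logm(T).real
    eps = 1e-7
    var = np.zeros((n, n))
    for j in range(n):
        pj = (c.counts[:, j] + 1.0) / (col[j] + n)
        cov = (np.diag(pj) - np.outer(pj, pj)) / n_eff[j]
        # sensitivity of every log(T) element to column-j perturbations
        grads = np.empty((n, n, n))
        for i in range(n):
            dT = np.zeros((n, n))
            dT[i, j] = eps
            grads[i] = (scipy.linalg.logm(T + dT).real - L0) / eps
        var += np.einsum("aij,ab,bij->ij", grads, cov, grads)
    se = np.sqrt(var) / c.lag * NS_PER_US
    np.fill_diagonal(se, np.nan)
    return se


def _check_irreducible(K: np.ndarray) -> None:
    g = nx.DiGraph()
    n = K.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and K[i, j] > 0:
                g.add_edge(j, i)
    comps = list(nx.strongly_connected_components(g))
    if len(comps) > 1:
        raise ReducibleGeneratorError(
            f"generator is reducible; communicating classes: "
            f"{[sorted(c) for c in comps]}"
        )


def stationary_distribution(k: RateMatrix) -> StationaryDistribution:
    """Stationary distribution p with K·p = 0, Σp = 1.

    Taken as the eigenvector of the eigenvalue closest to zero, which
    tolerates the small column-sum residuals of matrices transcribed at
    printed precision.
    """
    _check_irreducible(k.K)
    w, v = np.linalg.eig(k.K)
    i0 = int(np.argmin(np.abs(w)))
    p = v[:, i0].real
    p = np.abs(p)
    return StationaryDistribution(p=p / p.sum())


def relaxation_times(k: RateMatrix) -> np.ndarray:
    """Relaxation times τ_m = -1/λ_m in ns, slowest first.

    The single eigenvalue closest to zero (the stationary mode) is
    excluded. Eigenvalues with a significant imaginary part trigger a
    non-reversibility warning; their real parts are used.
    """
    w = np.linalg.eigvals(k.K)
    i0 = int(np.argmin(np.abs(w)))
    w = np.delete(w, i0)
    if np.any(np.abs(w.imag) > 1e-6 * np.abs(w.real).max()):
        warnings.warn(
            "complex relaxation eigenvalues: generator is significantly "
            "non-reversible",
            RuntimeWarning,
            stacklevel=2,
        )
    rates = -w.real  # μs⁻¹
    taus = NS_PER_US / rates
    return np.sort(taus)[::-1]


def implied_timescale_scan(
    traj: MicrostateTrajectory | list[MicrostateTrajectory],
    lags: list[float],
) -> pd.DataFrame:
    """Slowest implied timescale at each candidate lag (ns).

    A flat profile indicates Markovian behaviour at those lags; the lag
    choice itself is reported, not automated.
    """
    rows = []
    for lag in lags:
        c = count_transitions(traj, lag)
        K = rate_matrix_from_transition(transition_matrix(c))
        taus = relaxation_times(K)
        rows.append({"lag_ns": lag, "slowest_tau_ns": taus[0]})
    return pd.DataFrame(rows)


def read_rate_matrix_tsv(path) -> RateMatrix:
    """Read a generator laid out as in the printed tables (row i, col j = j->i)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RateMatrix(K=df.to_numpy(dtype=float))


def write_rate_matrix_tsv(path, k: RateMatrix) -> None:
    n = k.n_states
    pd.DataFrame(k.K, index=range(n), columns=range(n)).to_csv(path, sep="\t")
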