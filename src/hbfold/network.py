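"""Kinetic networks and global maximum weight (widest) folding paths.

Microstates become nodes annotated with stationary populations and free
energies ΔG_i = -RT ln(p_i/p_max); undirected edges carry the
detailed-balance-symmetrised reactive flux

    F_ij = (k_ij p_j + k_ji p_i) / 2.

The bottleneck of a path is its minimum-weight edge; a maximum weight
path (MWP) has the largest possible bottleneck, and a *global* MWP
additionally has the property that every contiguous sub-path is itself
an MWP between its endpoints. The GMWP is built by recursive widest-path
search: locate the bottleneck edge of an MWP, then refine the two halves
recursively.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PROFILE_TEMPERATURE, R_KCAL
from .kinetics import RateMatrix, StationaryDistribution


class NoPathError(ValueError):
    """Source and target not connected by positive-weight edges."""


@dataclass(frozen=True)
class KineticNetwork:
    """Undirected flux-weighted network over microstates.

    Attributes
    ----------
    weights : symmetric (n, n) matrix of non-negative edge weights;
        zeros denote absent edges.
    populations : stationary populations per node (may be None).
    free_energies : ΔG_i in kcal/mol relative to the most populated
        node (may be None).
    """

    weights: np.ndarray
    populations: np.ndarray | None = None
    free_energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("edge weights must be symmetric")
        if w.min() < 0:
            raise ValueError("edge weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.weights[i] > 0)


@dataclass(frozen=True)
class PathResult:
    path: tuple[int, ...]
    bottleneck_edge: tuple[int, int]
    bottleneck_weight: float


def flux_weights(k: RateMatrix, p: StationaryDistribution) -> KineticNetwork:
    """Symmetrised reactive-flux edge weights from rates and populations."""
    K, pv = k.K, p.p
    n = K.shape[0]
    if len(pv) != n:
        raise ValueError("dimension mismatch between K and p")
    F = (K * pv[None, :] + K.T * pv[:, None]) / 2.0
    np.fill_diagonal(F, 0.0)
    F[F < 0] = 0.0
    if np.any(pv == 0):
        warnings.warn(
            "nodes with zero stationary population carry no flux and are "
            "effectively excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    return KineticNetwork(
        weights=F, populations=pv,
        free_energies=free_energy_profile(p, PROFILE_TEMPERATURE),
    )


def free_energy_profile(
    p: StationaryDistribution | np.ndarray, temperature: float = PROFILE_TEMPERATURE
) -> np.ndarray:
    """ΔG_i = -RT ln(p_i / p_max), kcal/mol; zero-population nodes -> NaN."""
    pv = p.p if isinstance(p, StationaryDistribution) else np.asarray(p, dtype=float)
    if np.all(pv == 0):
        raise ValueError("all populations are zero")
    pmax = pv.max()
    with np.errstate(divide="ignore"):
        dG = -R_KCAL * temperature * np.log(pv / pmax)
    dG[pv == 0] = np.nan
    return dG


def _bottleneck_of(path: tuple[int, ...], W: np.ndarray) -> tuple[tuple[int, int], float]:
    """Minimum-weight edge along a path; earliest edge on ties."""
    best_edge, best_w = None, np.inf
    for a, b in zip(path[:-1], path[1:]):
        if W[a, b] < best_w:
            best_edge, best_w = (a, b), W[a, b]
    return best_edge, float(best_w)


def max_bottleneck_path(
    net: KineticNetwork, s: int, t: int, _forbidden: frozenset[int] = frozenset()
) -> PathResult:
    """Widest (maximum-bottleneck) simple path from s to t.

    Ties between equal-bottleneck paths are broken toward fewer edges,
    then the lexicographically smallest node sequence — deterministic by
    construction.
    """
    W = net.weights
    if s == t:
        raise ValueError("source and target must differ")
    # Bottleneck value: add edges in descending weight order until s-t connect.
    edges = [
        (W[i, j], i, j)
        for i in range(net.n_nodes)
        for j in range(i + 1, net.n_nodes)
        if W[i, j] > 0 and i not in _forbidden and j not in _forbidden
    ]
    edges.sort(key=lambda e: -e[0])
    parent = list(range(net.n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bstar = None
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
        if find(s) == find(t):
            bstar = w
            break
    if bstar is None:
        raise NoPathError(f"no positive-weight path connects {s} and {t}")
    # Fewest-hop, lexicographically smallest path using edges >= bstar.
    heap = [(0, (s,))]
    settled: set[int] = set()
    while heap:
        hops, path = heapq.heappop(heap)
        node = path[-1]
        if node == t:
            edge, bw = _bottleneck_of(path, W)
            return PathResult(path=path, bottleneck_edge=edge, bottleneck_weight=bw)
        if node in settled:
            continue
        settled.add(node)
        for nb in net.neighbors(node):
            if nb in settled or nb in _forbidden or nb in path:
                continue
            if W[node, nb] >= bstar:
                heapq.heappush(heap, (hops + 1, path + (int(nb),)))
    raise NoPathError(f"no path of bottleneck {bstar} found from {s} to {t}")


def gmwp(net: KineticNetwork, s: int, t: int) -> PathResult:
    """Global maximum weight path: recursive widest-path refinement.

    The MWP's bottleneck edge (u, v) is pinned; the (s, u) and (v, t)
    halves are then refined recursively, each restricted from re-using
    nodes committed to the other half, so the result is a simple path
    whose every contiguous sub-path is an MWP between its endpoints.
    """
    path = _gmwp_rec(net, s, t, frozenset())
    edge, bw = _bottleneck_of(path, net.weights)
    return PathResult(path=path, bottleneck_edge=edge, bottleneck_weight=bw)


def _gmwp_rec(
    net: KineticNetwork, s: int, t: int, forbidden: frozenset[int]
) -> tuple[int, ...]:
    mwp = max_bottleneck_path(net, s, t, _forbidden=forbidden)
    path = mwp.path
    if len(path) == 2:
        return path
    (u, v), _ = _bottleneck_of(path, net.weights)
    iu = path.index(u)
    try:
        left = (
            (s,) if u == s
            else _gmwp_rec(net, s, u, forbidden | frozenset(path[iu + 1:]))
        )
        right = (
            (t,) if v == t
            else _gmwp_rec(net, v, t, forbidden | frozenset(left))
        )
    except NoPathError:
        # exclusions disconnected a half; the MWP itself is the best
        # available refinement
        return path
    combined = left + right
    if len(set(combined)) != len(combined):  # pragma: no cover - guard
        return path
    return combined
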