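"""Committor functions and transition states.

The (forward) committor q_i is the probability that dynamics started in
microstate i reaches the helix set B before the coil set A. On a
continuous-time generator K (K[j, i] = rate i -> j) it satisfies

    Σ_j k(i->j) (q_j - q_i) = 0   for i outside A ∪ B,
    q = 0 on A,  q = 1 on B,

a linear system solved directly. Transition states are the states with
q ≈ 1/2 — equally likely to fold or unfold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import RateMatrix, TransitionMatrix


@dataclass(frozen=True)
class CommittorProfile:
    q: np.ndarray
    source_set: tuple[int, ...]  # A, coil side: q = 0
    sink_set: tuple[int, ...]  # B, helix side: q = 1

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.min() < -1e-9 or q.max() > 1 + 1e-9:
            raise ValueError("committor values must lie in [0, 1]")
        object.__setattr__(self, "q", np.clip(q, 0.0, 1.0))


def committor(
    k: RateMatrix | TransitionMatrix,
    a_set,
    b_set,
) -> CommittorProfile:
    """Solve the committor boundary-value problem on K (or on T - I).

    A discrete-time transition matrix may be supplied for cross-checks;
    its committor obeys the same equations with rates replaced by
    transition probabilities.
    """
    A = tuple(sorted(int(a) for a in a_set))
    B = tuple(sorted(int(b) for b in b_set))
    if set(A) & set(B):
        raise ValueError("source and sink sets must be disjoint")
    if not A or not B:
        raise ValueError("source and sink sets must be non-empty")
    if isinstance(k, TransitionMatrix):
        L = k.T - np.eye(k.T.shape[0])
    else:
        L = k.K
    n = L.shape[0]
    interior = [i for i in range(n) if i not in A and i not in B]
    q = np.zeros(n)
    q[list(B)] = 1.0
    if interior:
        # rate(i -> j) = L[j, i]
        M = np.zeros((len(interior), len(interior)))
        rhs = np.zeros(len(interior))
        idx = {i: r for r, i in enumerate(interior)}
        for i in interior:
            r = idx[i]
            for j in range(n):
                if j == i:
                    continue
                rate = L[j, i]
                M[r, r] -= rate
                if j in idx:
                    M[r, idx[j]] += rate
                elif j in B:
                    rhs[r] -= rate
        try:
            q[interior] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "committor system is singular; interior states may be "
                "disconnected from the boundary sets"
            ) from exc
    return CommittorProfile(q=q, source_set=A, sink_set=B)


def backward_committor(k: RateMatrix, a_set, b_set) -> CommittorProfile:
    """Probability of reaching A before B; for reversible dynamics
    forward + backward committor = 1."""
    prof = committor(k, b_set, a_set)
    return CommittorProfile(q=prof.q, source_set=tuple(sorted(a_set)),
                            sink_set=tuple(sorted(b_set)))


def transition_states(profile: CommittorProfile, band: float = 0.1) -> list[int]:
    """States with |q - 1/2| <= band, always including the closest one.

    Returns an empty list (with a warning) when there are no interior
    states at all.
    """
    if not 0.0 < band < 0.5:
        raise ValueError("band must lie in (0, 0.5)")
    boundary = set(profile.source_set) | set(profile.sink_set)
    interior = [i for i in range(len(profile.q)) if i not in boundary]
    if not interior:
        warnings.warn("no interior states; no transition state to report",
                      RuntimeWarning, stacklevel=2)
        return []
    dev = np.abs(profile.q - 0.5)
    ts = {i for i in interior if dev[i] <= band}
    ts.add(min(interior, key=lambda i: (dev[i], i)))
    return sorted(ts)
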