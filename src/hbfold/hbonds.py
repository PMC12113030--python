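"""The hydrogen-bond-count (NHB) reaction coordinate.

Per-frame O...N donor-acceptor distances for the candidate i -> i+4
helical bonds are mapped to continuous bond weights in [0, 1], summed to
the scalar coordinate NHB(t), and rounded to integer microstates
NHB = 0 .. MAXHB. The weight function is a cubic ramp: fully formed
below 3.2 Å, fully broken above 4.0 Å, and in between the Hermite
smoothstep — the unique cubic that is C¹ at both cutoffs:

    w(d) = 1 - 3 t² + 2 t³,   t = (d - 3.2) / 0.8

which is monotone non-increasing and passes through 1/2 at d = 3.6 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HB_BROKEN_CUTOFF, HB_FORMED_CUTOFF


class InvalidDistanceError(ValueError):
    """Non-physical (non-positive) O...N distance."""


class EmptyInputError(ValueError):
    """Empty trajectory where frames are required."""


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame O...N distances for all candidate helical bonds.

    Attributes
    ----------
    distances : (n_frames, maxhb) float array, Å
    dt : frame interval, ns
    labels : bond identifiers, one per column
    """

    distances: np.ndarray
    dt: float
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2:
            raise ValueError("distances must be a frames x bonds matrix")
        if d.size and not np.all(d > 0):
            raise InvalidDistanceError("all O...N distances must be positive")
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if self.labels is not None and len(self.labels) != d.shape[1]:
            raise ValueError("one label per bond column required")
        object.__setattr__(self, "distances", d)

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    @property
    def maxhb(self) -> int:
        return self.distances.shape[1]


@dataclass(frozen=True)
class NHBSeries:
    """Continuous hydrogen-bond-count coordinate with per-bond weights."""

    weights: np.ndarray
    nhb: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = np.asarray(self.nhb, dtype=float)
        if not np.allclose(w.sum(axis=1), n, atol=1e-12):
            raise ValueError("nhb must equal the row sums of weights")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "nhb", n)

    @property
    def maxhb(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class MicrostateTrajectory:
    """Integer NHB microstate sequence on a fixed time grid."""

    states: np.ndarray
    dt: float
    maxhb: int

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int64)
        if s.size and (s.min() < 0 or s.max() > self.maxhb):
            raise ValueError("states must lie in [0, maxhb]")
        object.__setattr__(self, "states", s)

    def __len__(self) -> int:
        return len(self.states)


def hbond_weight(d):
    """Cubic-interpolated bond weight for O...N distance(s) ``d`` in Å.

    Accepts scalars or arrays; returns values in [0, 1].
    """
    d = np.asarray(d, dtype=float)
    if d.size and not np.all(d > 0):
        raise InvalidDistanceError("distance must be positive")
    t = np.clip((d - HB_FORMED_CUTOFF) / (HB_BROKEN_CUTOFF - HB_FORMED_CUTOFF), 0.0, 1.0)
    w = 1.0 - 3.0 * t**2 + 2.0 * t**3
    return float(w) if w.ndim == 0 else w


def nhb_series(ds: DistanceSeries) -> NHBSeries:
    """Per-frame bond weights and their sum NHB(t)."""
    if ds.n_frames == 0:
        raise EmptyInputError("distance series has no frames")
    w = hbond_weight(ds.distances)
    return NHBSeries(weights=w, nhb=w.sum(axis=1), dt=ds.dt)


def helix_fraction(traj: NHBSeries | MicrostateTrajectory | np.ndarray, maxhb: int) -> float:
    """Trajectory-average helix content, mean(NHB) / MAXHB."""
    if maxhb <= 0:
        raise ValueError("maxhb must be positive")
    if isinstance(traj, NHBSeries):
        values = traj.nhb
    elif isinstance(traj, MicrostateTrajectory):
        values = traj.states
    else:
        values = np.asarray(traj, dtype=float)
    if len(values) == 0:
        raise EmptyInputError("empty trajectory")
    return float(np.mean(values) / maxhb)


def discretize(s: NHBSeries, maxhb: int | None = None) -> MicrostateTrajectory:
    """Assign each frame to the nearest integer microstate.

    Ties at half-integers round toward the higher state; results are
    clamped to [0, maxhb].
    """
    m = s.maxhb if maxhb is None else maxhb
    states = np.clip(np.floor(s.nhb + 0.5).astype(np.int64), 0, m)
    return MicrostateTrajectory(states=states, dt=s.dt, maxhb=m)


def read_distance_tsv(path, dt: float) -> DistanceSeries:
    """Load a frames x bonds O...N distance table (TSV with header row)."""
    df = pd.read_csv(path, sep="\t")
    return DistanceSeries(
        distances=df.to_numpy(dtype=float), dt=dt, labels=tuple(df.columns)
    )


def write_nhb_tsv(path, series: NHBSeries, traj: MicrostateTrajectory) -> None:
    """Write frame, nhb, state columns as TSV."""
    pd.DataFrame(
        {"frame": np.arange(len(traj)), "nhb": series.nhb, "state": traj.states}
    ).to_csv(path, sep="\t", index=False)
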