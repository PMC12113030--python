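"""Helix-boundary diffusion and friction from microstate hopping rates.

Growth or loss of one hydrogen bond moves the helix boundary by one
step of length a (the helical rise per residue, 1.5 Å by default).
Interpreting nearest-neighbour hopping as a discretised 1D diffusion,
the position-dependent diffusion coefficient on edge (i, i+1) is the
geometric-mean hopping form consistent with detailed balance,

    D_{i,i+1} = a² √( k(i->i+1) · k(i+1->i) ),

and the associated friction follows from the Einstein relation
f = k_B T / D, exactly, per edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, HELIX_RISE_ANGSTROM, KB_J
from .kinetics import RateMatrix

US_INV_TO_S_INV = 1e6


@dataclass(frozen=True)
class DiffusionProfile:
    """Per-edge diffusion (m² s⁻¹) and friction (kg s⁻¹) coefficients."""

    edges: tuple[tuple[int, int], ...]
    D: np.ndarray
    friction: np.ndarray
    D_avg: float
    D_spread: float
    f_avg: float
    f_spread: float
    step_length: float  # m
    temperature: float  # K


def diffusion_profile(
    k: RateMatrix,
    a: float = HELIX_RISE_ANGSTROM * 1e-10,
    temperature: float = DEFAULT_TEMPERATURE,
) -> DiffusionProfile:
    """Position-dependent D and friction along the NHB coordinate.

    Parameters
    ----------
    k : microstate rate matrix, μs⁻¹ (K[i, j] = rate j -> i).
    a : step length in metres (default: 1.5 Å helical rise).
    temperature : K.

    Edges whose forward or backward rate vanishes are excluded with a
    warning. Averages are arithmetic means over the included edges with
    the sample standard deviation as spread.
    """
    if a <= 0:
        raise ValueError("step length must be positive")
    K = k.K
    n = K.shape[0]
    edges, Ds = [], []
    for i in range(n - 1):
        kf = K[i + 1, i]  # i -> i+1, bond formation
        kb = K[i, i + 1]  # i+1 -> i, bond loss
        if kf <= 0 or kb <= 0:
            warnings.warn(
                f"edge ({i},{i + 1}) has a vanishing hopping rate; excluded",
                RuntimeWarning, stacklevel=2,
            )
            continue
        Ds.append(a * a * np.sqrt(kf * kb) * US_INV_TO_S_INV)
        edges.append((i, i + 1))
    D = np.asarray(Ds)
    fr = KB_J * temperature / D
    ddof = 1 if len(D) > 1 else 0
    return DiffusionProfile(
        edges=tuple(edges), D=D, friction=fr,
        D_avg=float(D.mean()), D_spread=float(D.std(ddof=ddof)),
        f_avg=float(fr.mean()), f_spread=float(fr.std(ddof=ddof)),
        step_length=a, temperature=temperature,
    )


def friction_summary(profile: DiffusionProfile) -> tuple[float, float]:
    """Mean per-edge friction k_B T / D and its sample spread, kg s⁻¹."""
    return profile.f_avg, profile.f_spread
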