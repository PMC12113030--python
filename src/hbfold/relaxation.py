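"""Autocorrelation analysis and the two-state folding model.

The NHB autocorrelation function decays on two scales: a fast one from
local bond fluctuations and a slow one from global folding/unfolding.
A two-exponential fit yields τ1 < τ2; the slow time combines with the
helix fraction f through the equilibrium constant K = f/(1-f) into
two-state folding/unfolding rates

    k_u = (1/τ2) · 1/(1+K),    k_f = (1/τ2) · K/(1+K)

so that k_u + k_f = 1/τ2 identically, and ΔG = -RT ln K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .constants import DEFAULT_TEMPERATURE, R_KCAL


class ZeroVarianceError(ValueError):
    """Constant series has no autocorrelation."""


class FitError(RuntimeError):
    """Two-exponential fit failed to converge."""


@dataclass(frozen=True)
class BiExpFit:
    """a1·exp(-t/τ1) + a2·exp(-t/τ2) with τ1 < τ2."""

    a1: float
    a2: float
    tau1: float
    tau2: float
    residual: float
    degenerate: bool = False  # single-exponential-like input


@dataclass(frozen=True)
class TwoStateModel:
    f: float
    Keq: float
    ku: float  # 1/ns
    kf: float  # 1/ns
    tau_u: float  # ns
    tau_f: float  # ns
    dG: float  # kcal/mol
    temperature: float  # K


def autocorrelation(series: np.ndarray, max_lag: float, dt: float) -> np.ndarray:
    """Normalised, mean-subtracted ACF up to ``max_lag`` ns.

    Uses the biased (divide by N) estimator, whose smoother tail is
    better behaved under exponential fitting.
    """
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    var = np.dot(x, x) / len(x)
    if var == 0:
        raise ZeroVarianceError("series is constant; ACF undefined")
    n_lags = int(round(max_lag / dt)) + 1
    if n_lags > len(x):
        raise ValueError("max_lag exceeds the series span")
    # FFT-based estimator; biased normalisation by N
    nfft = 1 << int(np.ceil(np.log2(2 * len(x))))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n_lags] / len(x)
    return acov / var


def _biexp(t, a1, a2, tau1, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def fit_biexponential(acf: np.ndarray, dt: float) -> BiExpFit:
    """Constrained least-squares two-exponential fit of an ACF.

    Deterministic initialisation from the first 1/e crossing: τ1 starts
    at crossing/5 and τ2 at 5x the crossing; amplitudes are bounded to
    [0, 1.5] and times to [dt, 10·t_max]. A fit whose two time scales
    collapse (ratio < 1.2) or whose fast amplitude vanishes is flagged
    degenerate.
    """
    y = np.asarray(acf, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 ACF points")
    t = np.arange(len(y)) * dt
    below = np.flatnonzero(y < np.exp(-1.0))
    crossing = t[below[0]] if below.size else t[-1] / 2
    crossing = max(crossing, dt)
    p0 = [0.5, 0.5, crossing / 5.0, crossing * 5.0]
    bounds = ([0.0, 0.0, dt / 10.0, dt / 10.0], [1.5, 1.5, 10 * t[-1], 10 * t[-1]])
    try:
        popt, _ = scipy.optimize.curve_fit(
            _biexp, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise FitError(f"two-exponential fit failed (init {p0}): {exc}") from exc
    a1, a2, tau1, tau2 = popt
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    residual = float(np.sqrt(np.mean((y - _biexp(t, a1, a2, tau1, tau2)) ** 2)))
    degenerate = tau2 / max(tau1, 1e-300) < 1.2 or min(a1, a2) < 1e-3
    return BiExpFit(
        a1=float(a1), a2=float(a2), tau1=float(tau1), tau2=float(tau2),
        residual=residual, degenerate=degenerate,
    )


def two_state_model(
    f: float, tau2: float, temperature: float = DEFAULT_TEMPERATURE
) -> TwoStateModel:
    """Two-state folding rates and free energy from f and the slow time."""
    if not 0.0 < f < 1.0:
        raise ValueError("helix fraction must lie strictly in (0, 1)")
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    Keq = f / (1.0 - f)
    ku = (1.0 / tau2) / (1.0 + Keq)
    kf = (1.0 / tau2) * Keq / (1.0 + Keq)
    dG = -R_KCAL * temperature * np.log(Keq)
    return TwoStateModel(
        f=f, Keq=Keq, ku=ku, kf=kf, tau_u=1.0 / ku, tau_f=1.0 / kf,
        dG=float(dG), temperature=temperature,
    )
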