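"""Exponential PO2 decay regression and the D50 statistic.

Each microwell's deoxygenation trace is modelled as PO2(t) = A·e^(−K·t),
with A the initial PO2 (mmHg) and K the decay constant (s⁻¹).  The
half-decay time D50 = ln(2)/K measures how long the well takes to lose half
its oxygen: an occupied well releases O2 into the well, slowing the decay
and raising D50.

Fitting is plain nonlinear least squares with K bounded to [1e-3, 50] s⁻¹
and an initial guess from a log-linear regression over the first two
seconds.  By default A is held fixed at the configured initial PO2, which
makes single-well fits a robust one-parameter problem; a free-amplitude
mode exists for amplitude-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .quench import PO2Trace

__all__ = ["DecayFit", "fit_exponential", "d50_from_k", "goodness_of_fit"]

#: Default initial PO2 of an air-equilibrated well, mmHg.
DEFAULT_INITIAL_PO2 = 155.3

K_BOUNDS = (1e-3, 50.0)  # s^-1
MIN_SAMPLES = 10


@dataclass(frozen=True)
class DecayFit:
    """Result of fitting PO2 = A·e^(−Kt) to one well.

    ``success`` is False for non-decaying or degenerate traces; such wells
    are excluded downstream, with the reason in ``failure_reason``.
    """

    A: float
    K: float
    r2: float
    d50: float
    a_fixed: bool
    success: bool = True
    failure_reason: str | None = None

    @classmethod
    def failed(cls, reason: str, a_fixed: bool) -> "DecayFit":
        return cls(
            A=math.nan, K=math.nan, r2=math.nan, d50=math.nan,
            a_fixed=a_fixed, success=False, failure_reason=reason,
        )


def d50_from_k(k: float) -> float:
    """Half-decay time D50 = ln(2)/K, seconds.  Requires K > 0."""
    if not k > 0:
        raise ValueError(f"K must be positive, got {k}")
    return math.log(2.0) / k


def _initial_k(t: np.ndarray, p: np.ndarray, a0: float) -> float:
    """Log-linear slope over the first 2 s, used only to seed the optimizer."""
    sel = (t <= 2.0) & (p > 0)
    if np.count_nonzero(sel) >= 2:
        slope = np.polyfit(t[sel], np.log(p[sel]), 1)[0]
        k0 = -slope
    else:
        k0 = 1.0
    return float(np.clip(k0, K_BOUNDS[0] * 10, K_BOUNDS[1] / 10))


def fit_exponential(
    trace: PO2Trace,
    fix_amplitude: float | None = None,
) -> DecayFit:
    """Fit PO2 = A·e^(−Kt) to a trace by bounded nonlinear least squares.

    Parameters
    ----------
    trace : PO2Trace
        Time in seconds from deoxygenation onset; at least 10 samples.
    fix_amplitude : float, optional
        Hold A fixed at this value (mmHg) and fit K alone.  When None both
        A and K are free.

    Returns
    -------
    DecayFit
        With ``success=False`` (never an exception) when the trace does not
        decay: best K at the lower bound, or zero-variance trace.
    """
    t = np.asarray(trace.time, dtype=float)
    p = np.asarray(trace.po2, dtype=float)
    if len(t) < MIN_SAMPLES:
        raise ValueError(f"well {trace.well_id}: need >= {MIN_SAMPLES} samples, got {len(t)}")
    if not (np.all(np.diff(t) > 0) and t[0] == 0):
        raise ValueError(f"well {trace.well_id}: time must strictly increase from 0")
    if fix_amplitude is not None and not fix_amplitude > 0:
        raise ValueError("fix_amplitude must be positive")

    a_fixed = fix_amplitude is not None
    if np.ptp(p) == 0:
        return DecayFit.failed("zero-variance trace", a_fixed)

    a0 = fix_amplitude if a_fixed else max(float(p[0]), 1e-6)
    k0 = _initial_k(t, p, a0)

    if a_fixed:
        res = least_squares(
            lambda x: fix_amplitude * np.exp(-x[0] * t) - p,
            x0=[k0], bounds=([K_BOUNDS[0]], [K_BOUNDS[1]]),
        )
        a_hat, k_hat = fix_amplitude, float(res.x[0])
    else:
        res = least_squares(
            lambda x: x[0] * np.exp(-x[1] * t) - p,
            x0=[a0, k0],
            bounds=([1e-6, K_BOUNDS[0]], [np.inf, K_BOUNDS[1]]),
        )
        a_hat, k_hat = float(res.x[0]), float(res.x[1])

    if not res.success:
        return DecayFit.failed(f"optimizer failed: {res.message}", a_fixed)
    # K pinned at the lower bound means the trace does not decay.
    if k_hat <= K_BOUNDS[0] * (1 + 1e-6):
        return DecayFit.failed("non-decaying trace (K at lower bound)", a_fixed)

    pred = a_hat * np.exp(-k_hat * t)
    r2 = _r_squared(p, pred)
    return DecayFit(A=a_hat, K=k_hat, r2=r2, d50=d50_from_k(k_hat), a_fixed=a_fixed)


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        return math.nan
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def goodness_of_fit(trace: PO2Trace, fit: DecayFit) -> float:
    """Coefficient of determination R² of *fit* on *trace*.

    R² = 1 − SSres/SStot; exactly 1 on noiseless model data, NaN for a
    zero-variance trace (flagged, not raised).
    """
    if not fit.success:
        raise ValueError("goodness_of_fit requires a successful fit")
    pred = fit.A * np.exp(-fit.K * np.asarray(trace.time, dtype=float))
    return _r_squared(np.asarray(trace.po2, dtype=float), pred)
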