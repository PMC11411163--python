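"""Closed-form mutant-fraction solutions and the released-payload proxy.

Because mutants never lyse, the mutant fraction ``f = y/(x+y)`` obeys the
logistic selection equation ``df/dt = alpha(t) f (1 - f)``.  Its solution is

    f(t) = 1 / (exp(C - int_0^t alpha dt') + 1),   C = ln(1/f0 - 1),

which for constant lysis rate alpha reduces to

    f(t) = e^{alpha t} / (1/f0 - 1 + e^{alpha t}).

The therapeutic payload released by lysis is proportional to the cumulative
lysed biomass; the proxy integrates the net population loss rate of the
therapeutic strain, ``int (alpha - gamma)^+ x dt`` (default), or the gross
lysis flux ``int alpha x dt`` — both are proportional proxies, not absolute
amounts, so only ratios of loads are meaningful.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .model import Trajectory

__all__ = [
    "fraction_constant_alpha",
    "fraction_general",
    "fraction_curve",
    "released_load",
    "takeover_time",
    "takeover_time_constant_alpha",
    "NOT_REACHED",
]

#: Sentinel returned by :func:`takeover_time` when the threshold is never crossed.
NOT_REACHED = "not reached"


def _check_f0(f0: float) -> None:
    if not 0 < f0 < 1:
        raise ValueError(f"f0 must be in (0, 1), got {f0}")


def fraction_constant_alpha(t, alpha: float, f0: float):
    """Mutant fraction at time ``t`` under a constant lysis rate.

    Exact solution of df/dt = alpha f (1-f) with f(0) = f0.
    """
    _check_f0(f0)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    # numerically stable logistic: f = 1 / (1 + (1/f0 - 1) e^{-alpha t})
    out = 1.0 / (1.0 + (1.0 / f0 - 1.0) * np.exp(-alpha * t_arr))
    return float(out) if np.isscalar(t) else out


def fraction_general(t: float, alpha_times, alpha_values, f0: float):
    """Mutant fraction at ``t`` for a time-varying lysis rate series.

    The integral of ``alpha`` over [0, t] is computed by trapezoidal
    quadrature on the supplied grid (which must cover [0, t]).
    """
    _check_f0(f0)
    ts = np.asarray(alpha_times, dtype=float)
    al = np.asarray(alpha_values, dtype=float)
    if ts.ndim != 1 or ts.shape != al.shape:
        raise ValueError("alpha series must be 1-D and aligned with its time grid")
    if t < ts[0] or t > ts[-1] + 1e-12:
        raise ValueError(f"alpha series on [{ts[0]}, {ts[-1]}] does not cover t={t}")
    mask = ts <= t
    ts_cut = np.append(ts[mask], t) if ts[mask][-1] < t else ts[mask]
    al_cut = np.append(al[mask], np.interp(t, ts, al)) if ts[mask][-1] < t else al[mask]
    integral = np.trapezoid(al_cut, ts_cut)
    C = math.log(1.0 / f0 - 1.0)
    # 1/(exp(C - I) + 1) computed stably for large I
    z = C - integral
    if z > 0:
        return 1.0 / (math.exp(z) + 1.0)
    ez = math.exp(z)
    return 1.0 / (ez + 1.0)


def fraction_curve(traj: Trajectory, f0: float = None) -> np.ndarray:
    """Quadrature mutant-fraction curve from a trajectory's own alpha(t)."""
    if f0 is None:
        f0 = float(traj.fraction_mutant[0])
    _check_f0(f0)
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (traj.alpha[1:] + traj.alpha[:-1]) * np.diff(traj.times))]
    )
    C = math.log(1.0 / f0 - 1.0)
    return 1.0 / (1.0 + np.exp(np.clip(C - integral, -700, 700)))


def released_load(traj: Trajectory, integrand: str = "net_lysis") -> np.ndarray:
    """Cumulative released-payload proxy along a trajectory.

    ``integrand="net_lysis"`` integrates (alpha - gamma)^+ x (net loss of the
    therapeutic strain, zero while growth outpaces lysis);
    ``integrand="lysis"`` integrates alpha x (gross lysis flux).  Trapezoidal
    quadrature on the trajectory grid; non-decreasing by construction.
    """
    if integrand == "net_lysis":
        rate = np.maximum(traj.alpha - traj.gamma, 0.0) * traj.x
    elif integrand == "lysis":
        rate = traj.alpha * traj.x
    else:
        raise ValueError("integrand must be 'net_lysis' or 'lysis'")
    dt = np.diff(traj.times)
    return np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])


def takeover_time(traj: Trajectory, threshold: float = 0.99) -> Union[float, str]:
    """First time the mutant fraction reaches ``threshold``.

    Linearly interpolated between grid points; returns :data:`NOT_REACHED`
    when the fraction stays below the threshold for the whole trajectory.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    f = traj.fraction_mutant
    if f[0] >= threshold:
        return float(traj.times[0])
    above = np.nonzero(f >= threshold)[0]
    if above.size == 0:
        return NOT_REACHED
    i = int(above[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    f0_, f1 = f[i - 1], f[i]
    return float(t0 + (threshold - f0_) / (f1 - f0_) * (t1 - t0))


def takeover_time_constant_alpha(alpha: float, f0: float,
                                 threshold: float = 0.99) -> float:
    """Takeover time by algebraic inversion of the constant-alpha solution."""
    _check_f0(f0)
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if f0 >= threshold:
        return 0.0
    if alpha <= 0:
        return math.inf
    return math.log(threshold * (1.0 / f0 - 1.0) / (1.0 - threshold)) / alpha
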