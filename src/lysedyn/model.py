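"""Core dynamical system: lysing therapeutic strain, escape mutants, toxin.

The model couples logistic growth with toxin-triggered self-lysis::

    dx/dt = (gamma - alpha) * x
    dy/dt = gamma * y
    dp/dt = beta([AHL]) - (gamma - alpha)^+ * p - delta * p

    gamma = gamma0 * (1 - (x + y)/rho_s)
    alpha = alpha0 * p^n / (K^n + p^n)
    beta  = beta0 * [AHL]^m / (k^m + [AHL]^m)

where ``(v)^+ = max(v, 0)`` prevents a negative dilution rate of the per-cell
toxin.  ``x`` is the therapeutic (lysing) strain, ``y`` the non-lysing escape
mutant, ``p`` the per-cell toxin concentration in therapeutic cells.  Because
the mutant never lyses, any induction selects for it: the mutant fraction
``f = y/(x+y)`` obeys ``df/dt = alpha * f * (1 - f)`` along trajectories.

Integration is by direct forward Euler on a uniform grid (the integrator the
analysis is defined with; the step-halving check in :func:`integrate` guards
the step size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import euler_run
from .params import ModelParams
from .programs import ConstantInduction, InductionProgram

__all__ = [
    "PopulationState",
    "Trajectory",
    "CrashSummary",
    "IntegrationError",
    "ConvergenceWarning",
    "hill",
    "beta_of_ahl",
    "rhs",
    "integrate",
    "crash_summary",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite state."""


class ConvergenceWarning(UserWarning):
    """Raised when halving the Euler step materially changes the trajectory."""


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous state: densities (a.u.), per-cell toxin (a.u.), time (h)."""

    x: float
    y: float
    p: float
    t: float = 0.0

    def __post_init__(self):
        if self.x < 0 or self.y < 0 or self.p < 0:
            raise ValueError("x, y and p must be non-negative")

    @classmethod
    def from_total(cls, total: float, fraction_mutant: float, p: float = 0.0,
                   t: float = 0.0) -> "PopulationState":
        """Split a total density into (therapeutic, mutant) by mutant fraction."""
        if not 0 <= fraction_mutant <= 1:
            raise ValueError("fraction_mutant must be in [0, 1]")
        return cls(x=total * (1.0 - fraction_mutant), y=total * fraction_mutant,
                   p=p, t=t)


def hill(value, threshold, coefficient):
    """Activating Hill function ``v^n / (T^n + v^n)``.

    Strictly increasing in ``value``; 0 at 0, 1/2 at the threshold, -> 1 as
    ``value`` -> infinity.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("hill input must be non-negative")
    if threshold <= 0:
        raise ValueError("hill threshold must be positive")
    if coefficient < 1:
        raise ValueError("hill coefficient must be >= 1")
    with np.errstate(over="ignore"):
        r = (v / threshold) ** coefficient
        out = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    return float(out) if np.isscalar(value) else out


def beta_of_ahl(ahl, params: ModelParams):
    """Inducer-dependent per-cell toxin production rate (h^-1 a.u.)."""
    a = np.asarray(ahl, dtype=float)
    if np.any(a < 0):
        raise ValueError("ahl must be non-negative")
    out = params.beta0 * np.where(a > 0, hill(np.maximum(a, 0), params.k, params.m), 0.0)
    return float(out) if np.isscalar(ahl) else out


def rhs(state: PopulationState, params: ModelParams, ahl: float,
        positive_part: str = "net_growth"):
    """Time derivatives (dx/dt, dy/dt, dp/dt) of the core model.

    ``positive_part`` selects the argument of the clamped toxin-dilution term:
    ``"net_growth"`` uses (gamma - alpha)^+ (default), ``"growth"`` uses
    (gamma)^+.
    """
    gamma = params.gamma0 * (1.0 - (state.x + state.y) / params.rho_s)
    alpha = params.alpha0 * hill(state.p, params.K, params.n)
    beta = beta_of_ahl(ahl, params)
    if positive_part == "net_growth":
        dil = max(gamma - alpha, 0.0)
    elif positive_part == "growth":
        dil = max(gamma, 0.0)
    else:
        raise ValueError("positive_part must be 'net_growth' or 'growth'")
    dx = (gamma - alpha) * state.x
    dy = gamma * state.y
    dp = beta - dil * state.p - params.delta * state.p
    return dx, dy, dp


_PP_MODES = {"net_growth": 0, "growth": 1}


@dataclass
class Trajectory:
    """A simulated trajectory on a uniform time grid, with derived series.

    Attributes
    ----------
    times : ndarray, h
    x, y, p : ndarray
        Therapeutic density, mutant density, per-cell toxin.
    ahl : ndarray
        Inducer level applied during the step starting at each grid time
        (last entry repeats for alignment).
    params, program
        The inputs the trajectory was generated with.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    ahl: np.ndarray
    params: ModelParams
    program: InductionProgram
    positive_part: str = "net_growth"
    n_clamped: int = 0
    s: Optional[np.ndarray] = None
    a: Optional[np.ndarray] = None
    load_integrand: str = field(default="net_lysis", repr=False)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def total(self) -> np.ndarray:
        """Total culture density x + y (what a plate reader sees)."""
        return self.x + self.y

    @property
    def fraction_mutant(self) -> np.ndarray:
        """Mutant fraction f = y / (x + y); defined as 1 where the culture is empty
        and y reached zero together with x (extinction keeps f at its last value)."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, self.y / np.where(tot > 0, tot, 1.0), np.nan)
        if np.any(np.isnan(f)):
            # carry the last defined value forward (empty culture)
            idx = np.where(np.isnan(f), 0, np.arange(f.size))
            np.maximum.accumulate(idx, out=idx)
            f = f[idx]
        return f

    @property
    def gamma(self) -> np.ndarray:
        g = self.params.gamma0 * (1.0 - self.total / self.params.rho_s)
        if self.s is not None and self.params.K_s is not None:
            g = g * self.s / (self.params.K_s + self.s)
        return g

    @property
    def alpha(self) -> np.ndarray:
        return self.params.alpha0 * hill(self.p, self.params.K, self.params.n)

    @property
    def released_load(self) -> np.ndarray:
        """Cumulative released-payload proxy (see :mod:`lysedyn.analytic`)."""
        from .analytic import released_load

        return released_load(self, integrand=self.load_integrand)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_h": self.times,
                "ahl_nM": self.ahl,
                "x": self.x,
                "y": self.y,
                "p": self.p,
                "total": self.total,
                "fraction_mutant": self.fraction_mutant,
                "released_load": self.released_load,
            }
        )
        if self.s is not None:
            df["substrate"] = self.s
        if self.a is not None:
            df["ahl_state_nM"] = self.a
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def sample(self, sample_times) -> np.ndarray:
        """Total density linearly interpolated at arbitrary times."""
        return np.interp(np.asarray(sample_times, dtype=float), self.times, self.total)

    def plot(self, ax=None, log: bool = False):
        """Plot x, y, total and toxin against time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.times, self.x, label="therapeutic x", color="tab:blue")
        ax.plot(self.times, self.y, label="mutant y", color="tab:orange")
        ax.plot(self.times, self.total, label="total", color="k", lw=1, ls="--")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("density (a.u.)")
        if log:
            ax.set_yscale("log")
        ax2 = ax.twinx()
        ax2.plot(self.times, self.p, color="tab:red", alpha=0.5, label="toxin p")
        ax2.set_ylabel("per-cell toxin (a.u.)")
        ax.legend(loc="upper left", fontsize=8)
        return ax


@dataclass(frozen=True)
class CrashSummary:
    """Lysis-crash phenomenology of a total-density curve.

    ``peak`` is the first local maximum (lysis onset), ``trough`` the
    subsequent local minimum (resumption of growth).  ``drop_percent`` is
    100 * (peak - trough) / peak.
    """

    peak_time: float
    peak_density: float
    trough_time: float
    trough_density: float
    drop_percent: float


def crash_summary(traj: Trajectory) -> Optional[CrashSummary]:
    """Locate the growth -> lysis crash -> regrowth signature, if present."""
    tot = traj.total
    d = np.diff(tot)
    ipk = None
    for i in range(1, d.size):
        if d[i - 1] > 0 and d[i] <= 0:
            ipk = i
            break
    if ipk is None:
        return None
    itr = None
    for i in range(ipk + 1, d.size):
        if d[i - 1] < 0 and d[i] >= 0:
            itr = i
            break
    if itr is None:
        return None
    return CrashSummary(
        peak_time=float(traj.times[ipk]),
        peak_density=float(tot[ipk]),
        trough_time=float(traj.times[itr]),
        trough_density=float(tot[itr]),
        drop_percent=float(100.0 * (tot[ipk] - tot[itr]) / tot[ipk]),
    )


def _run(params: ModelParams, program: InductionProgram, init: PopulationState,
         t_end: float, dt: float, positive_part: str, variant: int = 0,
         s0: float = 1.0, a0: float = 0.0):
    n_steps = int(round((t_end - init.t) / dt))
    times = init.t + dt * np.arange(n_steps + 1)
    levels = program.levels_on_grid(times[:-1])
    pp = _PP_MODES[positive_part]
    p_ = params
    x, y, p, s, a, n_clamped, bad = euler_run(
        init.x, init.y, init.p, s0, a0, levels, dt,
        p_.gamma0, p_.rho_s, p_.alpha0, p_.K, p_.n, p_.beta0, p_.k, p_.m,
        p_.delta,
        p_.mu if p_.mu is not None else 0.0,
        p_.r_s if p_.r_s is not None else 0.0,
        p_.K_s if p_.K_s is not None else 0.0,
        p_.d if p_.d is not None else 0.0,
        variant, pp,
    )
    if bad >= 0:
        raise IntegrationError(
            f"non-finite state encountered at t = {times[bad]:.6g} h"
        )
    ahl = np.append(levels, levels[-1]) if levels.size else np.zeros(1)
    return times, x, y, p, s, a, ahl, n_clamped


def integrate(params: ModelParams, program: InductionProgram,
              init: PopulationState, t_end: float, dt: float = 1e-3,
              positive_part: str = "net_growth",
              check_convergence: bool = False,
              convergence_rtol: float = 0.02) -> Trajectory:
    """Integrate the core model forward by direct Euler.

    Parameters
    ----------
    t_end : float
        End time (h); must exceed ``init.t``.
    dt : float
        Euler step (h).  The default 1e-3 h resolves the sharp lysis crash.
    positive_part : {"net_growth", "growth"}
        Reading of the clamped toxin-dilution term (see :func:`rhs`).
    check_convergence : bool
        If True, re-integrate at dt/2 and warn (:class:`ConvergenceWarning`)
        when peak density, peak/trough times or the final mutant fraction move
        by more than ``convergence_rtol`` (relative; times compared in units
        of the horizon).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= init.t:
        raise ValueError("t_end must exceed the initial time")
    if positive_part not in _PP_MODES:
        raise ValueError("positive_part must be 'net_growth' or 'growth'")

    times, x, y, p, s, a, ahl, n_clamped = _run(
        params, program, init, t_end, dt, positive_part
    )
    traj = Trajectory(times=times, x=x, y=y, p=p, ahl=ahl, params=params,
                      program=program, positive_part=positive_part,
                      n_clamped=n_clamped)

    if check_convergence:
        fine = integrate(params, program, init, t_end, dt / 2,
                         positive_part=positive_part, check_convergence=False)
        if not _summaries_agree(traj, fine, convergence_rtol):
            warnings.warn(
                f"halving dt from {dt:g} h changes the trajectory summary by "
                f"more than {convergence_rtol:g} (relative); reduce dt",
                ConvergenceWarning,
                stacklevel=2,
            )
    return traj


def _summaries_agree(coarse: Trajectory, fine: Trajectory, rtol: float) -> bool:
    horizon = coarse.times[-1] - coarse.times[0]
    cs, fs = crash_summary(coarse), crash_summary(fine)
    checks = []
    if (cs is None) != (fs is None):
        return False
    if cs is not None and fs is not None:
        checks += [
            abs(cs.peak_density - fs.peak_density) / max(fs.peak_density, 1e-30),
            abs(cs.peak_time - fs.peak_time) / horizon,
            abs(cs.trough_time - fs.trough_time) / horizon,
        ]
    fc, ff = coarse.fraction_mutant[-1], fine.fraction_mutant[-1]
    checks.append(abs(fc - ff) / max(ff, 1e-30) if ff > 1e-12 else abs(fc - ff))
    mc, mf = coarse.total.max(), fine.total.max()
    checks.append(abs(mc - mf) / max(mf, 1e-30))
    return max(checks) <= rtol
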