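"""Induction-schedule design: static versus pulsed (square-wave) induction.

Prolonged induction selects for non-lysing mutants, so the therapeutic
reservoir is eventually lost ("mutant takeover").  Pulsed induction trades
per-cycle payload against slower selection: each OFF interval lets the
therapeutic strain regrow before the next lysis bolus.  This module sweeps a
period x on-duration grid of square waves, accumulates the released-payload
proxy until takeover (or the horizon), and compares the best cell against the
static reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .analytic import NOT_REACHED, released_load, takeover_time
from .model import PopulationState, Trajectory, integrate
from .params import ModelParams
from .programs import ConstantInduction, InductionProgram, SquareWaveInduction

__all__ = [
    "StrategyEvaluation",
    "StrategyGrid",
    "evaluate_strategy",
    "sweep",
    "best_vs_static",
    "DEFAULT_PERIODS",
    "DEFAULT_ON_DURATIONS",
]

#: Default sweep grid: periods log-spaced 0.5-24 h, on-durations 0.1-6 h.
DEFAULT_PERIODS = np.logspace(np.log10(0.5), np.log10(24.0), 12)
DEFAULT_ON_DURATIONS = np.logspace(np.log10(0.1), np.log10(6.0), 12)


@dataclass(frozen=True)
class StrategyEvaluation:
    """Released load before takeover and the takeover time for one program."""

    load_before_takeover: float
    takeover_time: Union[float, str]  # h, or "not reached"
    final_fraction: float


def _truncated_load(traj: Trajectory, threshold: float,
                    integrand: str) -> StrategyEvaluation:
    load = released_load(traj, integrand=integrand)
    t_star = takeover_time(traj, threshold)
    if t_star == NOT_REACHED:
        return StrategyEvaluation(float(load[-1]), NOT_REACHED,
                                  float(traj.fraction_mutant[-1]))
    l_star = float(np.interp(t_star, traj.times, load))
    return StrategyEvaluation(l_star, float(t_star),
                              float(traj.fraction_mutant[-1]))


def evaluate_strategy(
    params: ModelParams,
    program: InductionProgram,
    init: PopulationState,
    horizon: float = 200.0,
    takeover_threshold: float = 0.99,
    dt: float = 1e-3,
    load_integrand: str = "net_lysis",
    positive_part: str = "net_growth",
) -> StrategyEvaluation:
    """Integrate the model under ``program`` and truncate the load at takeover.

    The released-payload proxy accumulates until the mutant fraction first
    reaches ``takeover_threshold`` (linearly interpolated), or until the
    horizon if takeover is never reached.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    traj = integrate(params, program, init, t_end=init.t + horizon, dt=dt,
                     positive_part=positive_part)
    return _truncated_load(traj, takeover_threshold, load_integrand)


@dataclass
class StrategyGrid:
    """Result of a period x on-duration square-wave sweep.

    ``loads[i, j]`` is the released load before takeover for
    ``periods[i], on_durations[j]``; cells with on-duration exceeding the
    period are invalid (NaN).  ``static_load`` is the constant-induction
    reference under the identical truncation rule.
    """

    periods: np.ndarray
    on_durations: np.ndarray
    amplitude: float
    loads: np.ndarray
    takeover_times: np.ndarray  # NaN where not reached
    static_load: float
    static_takeover: Union[float, str]
    takeover_threshold: float
    horizon: float
    threshold_ratios: Dict[float, float] = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.loads)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: period_h, on_h, load, takeover_h."""
        rows = []
        for i, P in enumerate(self.periods):
            for j, D in enumerate(self.on_durations):
                rows.append({
                    "period_h": float(P),
                    "on_h": float(D),
                    "load": float(self.loads[i, j]),
                    "takeover_h": float(self.takeover_times[i, j]),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot_heatmap(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        mesh = ax.pcolormesh(self.on_durations, self.periods,
                             np.ma.masked_invalid(self.loads), shading="nearest")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("on-duration (h)")
        ax.set_ylabel("period (h)")
        plt.colorbar(mesh, ax=ax, label="released load before takeover (a.u.)")
        return ax


def sweep(
    params: ModelParams,
    periods: Sequence[float] = DEFAULT_PERIODS,
    on_durations: Sequence[float] = DEFAULT_ON_DURATIONS,
    amplitude: float = 100.0,
    init: Optional[PopulationState] = None,
    horizon: float = 200.0,
    threshold: float = 0.99,
    dt: float = 1e-3,
    load_integrand: str = "net_lysis",
    positive_part: str = "net_growth",
    sensitivity_thresholds: Sequence[float] = (0.9, 0.99, 0.999),
) -> StrategyGrid:
    """Fill the strategy grid by repeated simulation; deterministic.

    ``sensitivity_thresholds`` additionally records the best-vs-static load
    ratio at alternative takeover definitions (computed from the same
    trajectories, so the extra cost is negligible).
    """
    periods = np.asarray(list(periods), dtype=float)
    on_durations = np.asarray(list(on_durations), dtype=float)
    if periods.size == 0 or on_durations.size == 0:
        raise ValueError("period and on-duration grids must be non-empty")
    if init is None:
        init = PopulationState.from_total(0.01, 7e-5)

    thresholds = list(dict.fromkeys([threshold, *sensitivity_thresholds]))
    static_traj = integrate(params, ConstantInduction(amplitude), init,
                            t_end=init.t + horizon, dt=dt,
                            positive_part=positive_part)
    static_eval = {thr: _truncated_load(static_traj, thr, load_integrand)
                   for thr in thresholds}

    loads = {thr: np.full((periods.size, on_durations.size), np.nan)
             for thr in thresholds}
    takeovers = np.full((periods.size, on_durations.size), np.nan)
    for i, P in enumerate(periods):
        for j, D in enumerate(on_durations):
            if D > P:
                continue
            program = (ConstantInduction(amplitude) if D == P
                       else SquareWaveInduction(amplitude, P, D))
            traj = integrate(params, program, init, t_end=init.t + horizon,
                             dt=dt, positive_part=positive_part)
            for thr in thresholds:
                ev = _truncated_load(traj, thr, load_integrand)
                loads[thr][i, j] = ev.load_before_takeover
                if thr == threshold:
                    takeovers[i, j] = (np.nan if ev.takeover_time == NOT_REACHED
                                       else ev.takeover_time)

    ratios = {}
    for thr in thresholds:
        with np.errstate(invalid="ignore"):
            mx = np.nanmax(loads[thr]) if np.any(~np.isnan(loads[thr])) else np.nan
        ref = static_eval[thr].load_before_takeover
        ratios[thr] = float(mx / ref) if ref > 0 else float("inf")

    ev0 = static_eval[threshold]
    return StrategyGrid(
        periods=periods, on_durations=on_durations, amplitude=amplitude,
        loads=loads[threshold], takeover_times=takeovers,
        static_load=ev0.load_before_takeover,
        static_takeover=ev0.takeover_time,
        takeover_threshold=threshold, horizon=horizon,
        threshold_ratios=ratios,
    )


def best_vs_static(grid: StrategyGrid) -> Tuple[float, float, float]:
    """Best grid cell and its load ratio to the static reference.

    Ties are broken toward the shortest on-duration, then the shortest
    period.  Raises on an all-invalid grid.
    """
    if not np.any(grid.valid):
        raise ValueError("grid contains no valid cells")
    best = None
    # enumerate in tie-break priority order: on-duration, then period
    for j in np.argsort(grid.on_durations, kind="stable"):
        for i in np.argsort(grid.periods, kind="stable"):
            v = grid.loads[i, j]
            if np.isnan(v):
                continue
            if best is None or v > best[0]:
                best = (v, i, j)
    load, i, j = best
    if grid.static_load <= 0:
        ratio = float("inf") if load > 0 else 1.0
    else:
        ratio = float(load / grid.static_load)
    return float(grid.periods[i]), float(grid.on_durations[j]), ratio
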