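"""Induction programs: the external inducer concentration [AHL](t).

The inducer is treated as an externally imposed forcing, constant between
breakpoints; the bacteria neither synthesise nor degrade it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class InductionProgram:
    """Base class: an evaluable inducer concentration profile, nM."""

    def ahl_at(self, t):
        """Inducer concentration at time(s) ``t`` (h); vectorised."""
        raise NotImplementedError

    def levels_on_grid(self, times: np.ndarray) -> np.ndarray:
        """Inducer level applied during each Euler step starting at ``times``."""
        return np.asarray(self.ahl_at(np.asarray(times, dtype=float)), dtype=float)


@dataclass(frozen=True)
class ConstantInduction(InductionProgram):
    """Static induction at a fixed concentration."""

    amplitude: float  # nM

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def ahl_at(self, t):
        t = np.asarray(t, dtype=float)
        return np.full_like(t, self.amplitude)


@dataclass(frozen=True)
class SquareWaveInduction(InductionProgram):
    """Periodic pulses: ON at ``amplitude`` for ``on_duration`` h each ``period`` h.

    Each cycle starts with the ON segment at t = 0.
    """

    amplitude: float  # nM
    period: float  # h
    on_duration: float  # h

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if not 0 <= self.on_duration <= self.period:
            raise ValueError("on_duration must satisfy 0 <= on_duration <= period")

    def ahl_at(self, t):
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period)
        return np.where(phase < self.on_duration, self.amplitude, 0.0)


@dataclass(frozen=True)
class PiecewiseInduction(InductionProgram):
    """Piecewise-constant profile: ``levels[i]`` holds from ``breakpoints[i]``.

    ``breakpoints`` must start at 0 and be strictly increasing; the last level
    extends to infinity.
    """

    breakpoints: Sequence[float] = field(default=())
    levels: Sequence[float] = field(default=())

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        if bp.size == 0 or bp.size != lv.size:
            raise ValueError("breakpoints and levels must be non-empty and equal-length")
        if bp[0] != 0:
            raise ValueError("first breakpoint must be 0")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(lv < 0):
            raise ValueError("levels must be >= 0")

    def ahl_at(self, t):
        t = np.asarray(t, dtype=float)
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        idx = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, lv.size - 1)
        return lv[idx]


def program_from_dict(d: dict) -> InductionProgram:
    """Build a program from a flat config mapping (``kind`` selects the type)."""
    kind = d.get("kind")
    if kind == "constant":
        return ConstantInduction(amplitude=float(d["amplitude"]))
    if kind == "square_wave":
        return SquareWaveInduction(
            amplitude=float(d["amplitude"]),
            period=float(d["period"]),
            on_duration=float(d["on_duration"]),
        )
    if kind == "piecewise":
        return PiecewiseInduction(
            breakpoints=tuple(float(b) for b in d["breakpoints"]),
            levels=tuple(float(v) for v in d["levels"]),
        )
    raise ValueError(f"unknown program kind {kind!r}")
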