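"""Synthetic plate-reader growth-curve data.

No public growth-curve dataset accompanies this circuit, so every fitting and
estimation stage is exercised on data generated from the model itself:
triplicate OD600-like curves sampled every 10 min over ~23 h across log-spaced
inducer concentrations, with the characteristic growth -> lysis crash ->
mutant regrowth shape, plus a configurable measurement-noise model
(multiplicative lognormal + additive Gaussian baseline + constant blank
offset, mimicking typical plate-reader behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import PopulationState, Trajectory, integrate
from .params import ModelParams
from .programs import ConstantInduction

__all__ = [
    "NoiseModel",
    "GrowthCurveSet",
    "read_growth_curves",
    "write_growth_curves",
    "generate_plate_reader",
    "generate_passaging_series",
    "generate_beta_calibration",
]

GROWTH_CURVE_COLUMNS = ["time_h", "od600", "ahl_nM", "replicate", "condition"]


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader measurement noise.

    od = total * LogNormal(cv=multiplicative_cv) + N(0, additive_sd)
         + baseline_offset, clipped at 0.

    ``seed`` makes draws reproducible; identical seeds give identical data.
    """

    multiplicative_cv: float = 0.03
    additive_sd: float = 0.002
    baseline_offset: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(clean, dtype=float).copy()
        if self.multiplicative_cv > 0:
            sigma = np.sqrt(np.log1p(self.multiplicative_cv**2))
            out = out * rng.lognormal(-0.5 * sigma**2, sigma, size=out.shape)
        if self.additive_sd > 0:
            out = out + rng.normal(0.0, self.additive_sd, size=out.shape)
        out = out + self.baseline_offset
        return np.maximum(out, 0.0)


NO_NOISE = NoiseModel(multiplicative_cv=0.0, additive_sd=0.0, baseline_offset=0.0)


@dataclass
class GrowthCurveSet:
    """Plate-reader-style replicate OD time series keyed by inducer level.

    Thin wrapper around a tidy DataFrame with columns
    ``time_h, od600, ahl_nM, replicate, condition``.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in GROWTH_CURVE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"growth-curve table missing columns: {missing}")
        if (self.data["od600"] < 0).any():
            raise ValueError("densities must be >= 0")
        if (self.data["time_h"] < 0).any():
            raise ValueError("times must be >= 0")
        for (_, _), g in self.data.groupby(["condition", "replicate"]):
            if not g["time_h"].is_monotonic_increasing:
                raise ValueError("times must be sorted within each replicate")

    @property
    def conditions(self):
        return sorted(self.data["condition"].unique())

    @property
    def ahl_levels(self) -> np.ndarray:
        return np.sort(self.data["ahl_nM"].unique())

    def for_condition(self, condition) -> pd.DataFrame:
        return self.data[self.data["condition"] == condition]

    def to_csv(self, path) -> None:
        write_growth_curves(self, path)

    @classmethod
    def from_csv(cls, path) -> "GrowthCurveSet":
        return read_growth_curves(path)


def write_growth_curves(gcs: GrowthCurveSet, path) -> None:
    """Write the canonical tab-delimited growth-curve format."""
    gcs.data.to_csv(path, sep="\t", index=False)


def read_growth_curves(path) -> GrowthCurveSet:
    """Read the canonical tab-delimited growth-curve format."""
    df = pd.read_csv(Path(path), sep="\t")
    return GrowthCurveSet(df[GROWTH_CURVE_COLUMNS])


def generate_plate_reader(
    params: ModelParams,
    ahl_list: Sequence[float],
    f0: float = 7e-5,
    duration: float = 23.0,
    interval: float = 1.0 / 6.0,
    replicates: int = 3,
    noise: NoiseModel = NO_NOISE,
    initial_density: float = 0.01,
    dt: float = 1e-3,
) -> GrowthCurveSet:
    """Simulate a plate-reader experiment across inducer conditions.

    Each condition starts from total density ``initial_density`` split as
    (1 - f0, f0) with no pre-induced toxin, is integrated under constant
    induction, sampled every ``interval`` h, and measurement noise applied
    per replicate.
    """
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = noise.rng()
    sample_times = np.arange(0.0, duration + 1e-9, interval)
    rows = []
    for ci, ahl in enumerate(ahl_list):
        traj = integrate(params, ConstantInduction(float(ahl)),
                         PopulationState.from_total(initial_density, f0),
                         t_end=duration, dt=dt)
        clean = traj.sample(sample_times)
        for rep in range(replicates):
            od = noise.apply(clean, rng)
            rows.append(pd.DataFrame({
                "time_h": sample_times,
                "od600": od,
                "ahl_nM": float(ahl),
                "replicate": rep,
                "condition": f"ahl_{ahl:g}",
            }))
    return GrowthCurveSet(pd.concat(rows, ignore_index=True))


def generate_passaging_series(
    params: ModelParams,
    ahl_schedule: Sequence[Tuple[float, float]],
    dilution_factor: float = 100.0,
    f0: float = 7e-5,
    noise: NoiseModel = NO_NOISE,
    initial_density: float = 0.01,
    interval: float = 1.0 / 6.0,
    replicates: int = 1,
    dt: float = 1e-3,
) -> GrowthCurveSet:
    """Simulate consecutive growth legs with dilution into fresh medium.

    ``ahl_schedule`` is a list of (duration h, ahl nM) legs.  At each passage
    the population densities are divided by ``dilution_factor`` while the
    per-cell toxin ``p`` is carried over unchanged (dilution of the culture
    does not change the intracellular concentration).  Legs are labelled
    ``leg0, leg1, ...`` in the condition column, with cumulative time.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    rng = noise.rng()
    rows = []
    state = PopulationState.from_total(initial_density, f0)
    t_offset = 0.0
    clean_per_leg = []
    for li, (dur, ahl) in enumerate(ahl_schedule):
        traj = integrate(params, ConstantInduction(float(ahl)), state,
                         t_end=state.t + dur, dt=dt)
        sample_times = np.arange(traj.times[0], traj.times[-1] + 1e-9, interval)
        clean_per_leg.append((li, ahl, sample_times, traj.sample(sample_times)))
        end = PopulationState(
            x=float(traj.x[-1]) / dilution_factor,
            y=float(traj.y[-1]) / dilution_factor,
            p=float(traj.p[-1]),
            t=float(traj.times[-1]),
        )
        state = end
        t_offset = float(traj.times[-1])
    for rep in range(replicates):
        for li, ahl, sample_times, clean in clean_per_leg:
            od = noise.apply(clean, rng)
            rows.append(pd.DataFrame({
                "time_h": sample_times,
                "od600": od,
                "ahl_nM": float(ahl),
                "replicate": rep,
                "condition": f"leg{li}",
            }))
    return GrowthCurveSet(pd.concat(rows, ignore_index=True))


def generate_beta_calibration(
    true_beta0: float,
    true_k: float,
    true_m: float,
    ahl_list: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy (ahl, beta) calibration pairs from an activating Hill curve.

    Emulates an in-vitro promoter characterisation: the production rate at
    each inducer level, with multiplicative lognormal noise of the given CV.
    """
    ahl = np.asarray(list(ahl_list), dtype=float)
    if ahl.size == 0:
        raise ValueError("ahl_list must be non-empty")
    from .model import beta_of_ahl
    from .params import ModelParams

    p = ModelParams(gamma0=1, rho_s=1, alpha0=0, K=1, n=1,
                    beta0=true_beta0, k=true_k, m=true_m, delta=0)
    beta = beta_of_ahl(ahl, p)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        beta = beta * rng.lognormal(-0.5 * sigma**2, sigma, size=beta.shape)
    return pd.DataFrame({"ahl_nM": ahl, "beta": beta})
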