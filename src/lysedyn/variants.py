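"""Model extensions: substrate consumption, adaptive mutation, dilution.

Three structural extensions of the core system, each reducing exactly to the
core model in the corresponding parameter limit:

* substrate — growth carries a Monod factor s/(K_s + s) with uptake
  ds/dt = -r_s (x+y) s/(K_s+s); s is normalised to s(0) = 1.  Reduces to the
  core model as K_s -> 0 with s = 1 (or r_s = 0).
* mutation — an adaptive mutation flux mu*x converts therapeutic cells into
  mutants: dx/dt gains -mu x, dy/dt gains +mu x.  Reduces to core at mu = 0.
* dilution — chemostat-style washout at rate d acts on both strains, and the
  inducer becomes a state with da/dt = supply - d*a; toxin production reads
  the inducer state.  Reduces to core at d = 0 with zero supply and a fixed.

The Monod placement (multiplying growth, consumption proportional to growth
activity) and the chemostat form of the dilution terms are this package's
reconstructions of those named extensions; every structural choice is
confined to this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._kernels import euler_run
from .model import (IntegrationError, PopulationState, Trajectory, beta_of_ahl,
                    hill)
from .params import ModelParams
from .programs import ConstantInduction, InductionProgram

__all__ = [
    "ExtendedState",
    "SteadyStateResult",
    "rhs_substrate",
    "rhs_mutation",
    "rhs_dilution",
    "integrate_variant",
    "find_steady_state",
    "VARIANTS",
]

VARIANTS = {"core": 0, "substrate": 1, "mutation": 2, "dilution": 3}


@dataclass(frozen=True)
class ExtendedState:
    """Population state extended with substrate s (normalised) and inducer a (nM)."""

    x: float
    y: float
    p: float
    s: float = 1.0
    a: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        if min(self.x, self.y, self.p, self.a) < 0:
            raise ValueError("x, y, p and a must be non-negative")
        if not 0 <= self.s <= 1:
            raise ValueError("substrate s must lie in [0, 1]")

    @property
    def fraction_mutant(self) -> float:
        tot = self.x + self.y
        return self.y / tot if tot > 0 else float("nan")


def _core_terms(state, params: ModelParams, ahl: float, monod: float = 1.0):
    gamma = params.gamma0 * (1.0 - (state.x + state.y) / params.rho_s) * monod
    alpha = params.alpha0 * hill(state.p, params.K, params.n)
    beta = beta_of_ahl(ahl, params)
    dil = max(gamma - alpha, 0.0)
    return gamma, alpha, beta, dil


def rhs_substrate(state: ExtendedState, params: ModelParams, ahl: float):
    """Derivatives (dx, dy, dp, ds) of the Monod substrate-consumption variant."""
    if params.r_s is None or params.K_s is None:
        raise ValueError("substrate variant requires params.r_s and params.K_s")
    monod = state.s / (params.K_s + state.s) if (params.K_s + state.s) > 0 else 0.0
    gamma, alpha, beta, dil = _core_terms(state, params, ahl, monod)
    dx = (gamma - alpha) * state.x
    dy = gamma * state.y
    dp = beta - dil * state.p - params.delta * state.p
    ds = -params.r_s * (state.x + state.y) * monod
    return dx, dy, dp, ds


def rhs_mutation(state, params: ModelParams, ahl: float):
    """Derivatives (dx, dy, dp) with the adaptive mutation flux mu*x."""
    if params.mu is None:
        raise ValueError("mutation variant requires params.mu")
    gamma, alpha, beta, dil = _core_terms(state, params, ahl)
    dx = (gamma - alpha) * state.x - params.mu * state.x
    dy = gamma * state.y + params.mu * state.x
    dp = beta - dil * state.p - params.delta * state.p
    return dx, dy, dp


def rhs_dilution(state: ExtendedState, params: ModelParams, ahl_supply: float):
    """Derivatives (dx, dy, dp, da) of the chemostat-dilution variant.

    ``ahl_supply`` is the inducer supply rate (nM/h); toxin production is
    evaluated at the inducer state ``a``.
    """
    if params.d is None:
        raise ValueError("dilution variant requires params.d")
    gamma, alpha, beta, dil = _core_terms(state, params, state.a)
    dx = (gamma - alpha - params.d) * state.x
    dy = (gamma - params.d) * state.y
    dp = beta - dil * state.p - params.delta * state.p
    da = ahl_supply - params.d * state.a
    return dx, dy, dp, da


def integrate_variant(
    params: ModelParams,
    variant: str,
    forcing: Union[float, InductionProgram],
    init: Union[PopulationState, ExtendedState],
    t_end: float,
    dt: float = 1e-3,
    positive_part: str = "net_growth",
) -> Trajectory:
    """Forward-Euler integration of a model variant.

    ``forcing`` is the inducer concentration program (core/substrate/mutation)
    or the inducer supply rate in nM/h (dilution); a bare float is promoted to
    a constant.  Returns a :class:`Trajectory` whose ``s``/``a`` series are
    populated when the variant uses them.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {sorted(VARIANTS)}")
    code = VARIANTS[variant]
    if variant == "substrate" and (params.r_s is None or params.K_s is None):
        raise ValueError("substrate variant requires params.r_s and params.K_s")
    if variant == "mutation" and params.mu is None:
        raise ValueError("mutation variant requires params.mu")
    if variant == "dilution" and params.d is None:
        raise ValueError("dilution variant requires params.d")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= init.t:
        raise ValueError("t_end must exceed the initial time")

    program = (ConstantInduction(float(forcing))
               if not isinstance(forcing, InductionProgram) else forcing)
    s0 = getattr(init, "s", 1.0)
    a0 = getattr(init, "a", 0.0)
    n_steps = int(round((t_end - init.t) / dt))
    times = init.t + dt * np.arange(n_steps + 1)
    levels = program.levels_on_grid(times[:-1])
    pp = {"net_growth": 0, "growth": 1}[positive_part]
    p_ = params
    x, y, p, s, a, n_clamped, bad = euler_run(
        init.x, init.y, init.p, s0, a0, levels, dt,
        p_.gamma0, p_.rho_s, p_.alpha0, p_.K, p_.n, p_.beta0, p_.k, p_.m,
        p_.delta,
        p_.mu or 0.0, p_.r_s or 0.0, p_.K_s or 0.0, p_.d or 0.0,
        code, pp,
    )
    if bad >= 0:
        raise IntegrationError(f"non-finite state at t = {times[bad]:.6g} h")
    ahl = np.append(levels, levels[-1]) if levels.size else np.zeros(1)
    return Trajectory(
        times=times, x=x, y=y, p=p, ahl=ahl, params=params, program=program,
        positive_part=positive_part, n_clamped=n_clamped,
        s=s if variant == "substrate" else None,
        a=a if variant == "dilution" else None,
    )


@dataclass
class SteadyStateResult:
    """Outcome of the long-horizon steady-state search."""

    state: ExtendedState
    fraction_mutant: float
    converged: bool
    residual: float  # relative derivative norm at the final state
    reason: str  # "converged" | "oscillatory" | "divergent" | "horizon"


def _variant_rhs_norm(variant: str, state: ExtendedState, params: ModelParams,
                      forcing: float) -> float:
    if variant == "substrate":
        d = rhs_substrate(state, params, forcing)
    elif variant == "mutation":
        d = rhs_mutation(state, params, forcing)
    elif variant == "dilution":
        d = rhs_dilution(state, params, forcing)
    else:
        from .model import rhs as core_rhs

        d = core_rhs(PopulationState(state.x, state.y, state.p), params, forcing)
    z = [state.x, state.y, state.p] + ([state.s] if variant == "substrate" else []) \
        + ([state.a] if variant == "dilution" else [])
    return max(abs(dz) / (1.0 + abs(v)) for dz, v in zip(d, z))


def find_steady_state(
    params: ModelParams,
    variant: str = "core",
    forcing: float = 0.0,
    init: Optional[ExtendedState] = None,
    tol: float = 1e-8,
    horizon_cap: float = 1e4,
    dt: float = 0.01,
    chunk: float = 100.0,
) -> SteadyStateResult:
    """Integrate until the relative derivative norm falls below ``tol``.

    The trajectory is advanced in chunks; convergence is declared when
    max_i |dz_i/dt| / (1 + |z_i|) < tol.  Oscillatory non-convergence
    (residual stops decreasing) is reported distinctly from divergence
    (state norm grows without bound).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if init is None:
        init = ExtendedState(x=0.01 * (1 - 7e-5), y=0.01 * 7e-5, p=0.0)
    state = init
    t = init.t
    history = []
    while t < init.t + horizon_cap:
        traj = integrate_variant(params, variant, forcing,
                                 _as_ext(state, t), t + chunk, dt=dt)
        state = ExtendedState(
            x=float(traj.x[-1]), y=float(traj.y[-1]), p=float(traj.p[-1]),
            s=float(np.clip(traj.s[-1], 0, 1)) if traj.s is not None else 1.0,
            a=float(traj.a[-1]) if traj.a is not None else getattr(state, "a", 0.0),
            t=float(traj.times[-1]),
        )
        t = state.t
        res = _variant_rhs_norm(variant, state, params, forcing)
        history.append(res)
        if res < tol:
            return SteadyStateResult(state, state.fraction_mutant, True, res,
                                     "converged")
        if max(state.x, state.y, state.p, state.a) > 1e9:
            return SteadyStateResult(state, state.fraction_mutant, False, res,
                                     "divergent")
        if len(history) >= 5 and history[-1] >= 0.5 * max(history[-5:-1]):
            # residual has stopped shrinking well above tol
            if history[-1] > 1e3 * tol and len(history) >= 10:
                return SteadyStateResult(state, state.fraction_mutant, False,
                                         res, "oscillatory")
    return SteadyStateResult(state, state.fraction_mutant, False,
                             history[-1] if history else float("inf"), "horizon")


def _as_ext(state, t: float) -> ExtendedState:
    return ExtendedState(x=state.x, y=state.y, p=state.p,
                         s=getattr(state, "s", 1.0), a=getattr(state, "a", 0.0),
                         t=t)
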