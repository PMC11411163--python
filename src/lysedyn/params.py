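"""Model parameters for the lysis-circuit population model.

The core model tracks a therapeutic (lysing) strain ``x``, an escape-mutant
(non-lysing) strain ``y`` and the per-cell intracellular toxin concentration
``p``.  Growth is logistic with shared carrying capacity, lysis is a Hill
function of toxin, and toxin production is a Hill function of the external
inducer (AHL) concentration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and Hill parameters of the lysis-circuit model.

    Parameters
    ----------
    gamma0 : float
        Maximum (exponential-phase) growth rate, h^-1.
    rho_s : float
        Carrying capacity of the culture, a.u. density.
    alpha0 : float
        Maximum toxin-induced lysis rate, h^-1.
    K : float
        Lysis Hill threshold, a.u. toxin concentration.
    n : float
        Lysis Hill cooperativity (>= 1).
    beta0 : float
        Maximum per-cell toxin production rate, h^-1 a.u.
    k : float
        Induction Hill threshold, nM AHL.
    m : float
        Induction Hill cooperativity (>= 1).
    delta : float
        Intracellular toxin degradation rate, h^-1.
    mu : float, optional
        Adaptive mutation rate therapeutic -> mutant, h^-1 (variant model).
    r_s : float, optional
        Substrate utilisation rate, h^-1 (Monod variant).
    K_s : float, optional
        Monod half-saturation constant, normalised substrate units.
    d : float, optional
        Dilution (washout) rate, h^-1 (chemostat variant).
    """

    gamma0: float
    rho_s: float
    alpha0: float
    K: float
    n: float
    beta0: float
    k: float
    m: float
    delta: float
    mu: Optional[float] = None
    r_s: Optional[float] = None
    K_s: Optional[float] = None
    d: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("gamma0", "rho_s", "alpha0", "K", "beta0", "k", "delta"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.rho_s <= 0:
            raise ValueError("rho_s must be > 0")
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        for name in ("mu", "r_s", "K_s", "d"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 if set, got {v}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Mean fitted parameter set of the reference plate-reader characterisation:
#: growth/lysis parameters from joint growth-curve fits, induction Hill from the
#: promoter calibration, delta set a priori in the slow-degradation range, and
#: the variant rates (substrate utilisation, adaptive mutation) used alongside.
FITTED_MEANS = ModelParams(
    gamma0=1.57,
    rho_s=0.33,
    alpha0=1.39,
    K=3.29,
    n=4.46,
    beta0=6.1,
    k=19.0,
    m=1.0,
    delta=0.1,
    mu=1e-7,
    r_s=4.17,
    K_s=0.1,
)

PRESETS = {"fitted_means": FITTED_MEANS}


def get_preset(name: str) -> ModelParams:
    """Look up a named parameter preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
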