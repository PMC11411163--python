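"""Parameter estimation from growth-curve data.

Each estimation task is a Model class constructed from data whose ``fit()``
returns a Results object carrying estimates, standard errors, diagnostics and
a ``summary()`` table:

* :class:`HillInductionModel` — activating Hill fit of the measured toxin
  production rate against inducer concentration (beta0, k, m).
* :class:`GrowthCurveModel` — joint fit of the full dynamical model to
  plate-reader curves across inducer conditions (shared parameters,
  per-condition inducer level), bounded least squares with Latin-hypercube
  multi-starts.
* :class:`MutantFractionModel` — the two-parameter (x0, y0) fit that reads the
  initial mutant fraction of a culture off a single 100 nM growth curve; all
  rate parameters held fixed.
* :class:`FractionInductionModel` — fit of the constant-lysis-rate mutant
  fraction solution to f(t_ind) points; exactly linear on the logit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from ._kernels import euler_run
from .model import beta_of_ahl, hill
from .params import ModelParams
from .synthetic import GrowthCurveSet

__all__ = [
    "EstimationError",
    "FitResult",
    "HillInductionModel",
    "GrowthCurveModel",
    "MutantFractionModel",
    "MutantFractionEstimate",
    "FractionInductionModel",
]


class EstimationError(RuntimeError):
    """Raised for degenerate designs or non-convergent fits."""


@dataclass
class FitResult:
    """Estimates with uncertainties from a least-squares fit."""

    params: Dict[str, float]
    bse: Dict[str, float]
    ssr: float
    nobs: int
    converged: bool
    fixed: Dict[str, float] = field(default_factory=dict)
    restart_ssr: Optional[np.ndarray] = None
    message: str = ""

    @property
    def restart_dispersion(self) -> float:
        """Spread of the objective across multi-start restarts (0 if single)."""
        if self.restart_ssr is None or len(self.restart_ssr) < 2:
            return 0.0
        return float(np.std(self.restart_ssr))

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            f"  nobs = {self.nobs}   SSR = {self.ssr:.6g}   converged = {self.converged}",
        ]
        lines.append(f"  {'parameter':>12s} {'estimate':>12s} {'std err':>12s}")
        for name, val in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:>12s} {val:>12.6g} {se:>12.4g}")
        if self.fixed:
            fx = ", ".join(f"{k}={v:g}" for k, v in self.fixed.items())
            lines.append(f"  fixed: {fx}")
        if self.message:
            lines.append(f"  note: {self.message}")
        return "\n".join(lines)


def _gn_cov(jac: np.ndarray, ssr: float, nobs: int) -> np.ndarray:
    """Gauss-Newton covariance at the optimum."""
    dof = max(nobs - jac.shape[1], 1)
    s2 = ssr / dof
    JTJ = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    return cov


# ---------------------------------------------------------------------------
# Hill calibration fit
# ---------------------------------------------------------------------------

class HillInductionModel:
    """Fit beta([AHL]) = beta0 [AHL]^m / (k^m + [AHL]^m) to calibration pairs.

    Requires at least 4 distinct inducer levels spanning the threshold region.
    """

    def __init__(self, ahl_values: Sequence[float], beta_estimates: Sequence[float]):
        self.ahl = np.asarray(list(ahl_values), dtype=float)
        self.beta = np.asarray(list(beta_estimates), dtype=float)
        if self.ahl.shape != self.beta.shape or self.ahl.ndim != 1:
            raise ValueError("ahl and beta must be aligned 1-D sequences")
        if np.any(self.ahl < 0):
            raise ValueError("ahl values must be >= 0")
        if np.unique(self.ahl).size < 4:
            raise EstimationError(
                "need >= 4 distinct inducer levels to identify (beta0, k, m)"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HillInductionModel":
        return cls(df["ahl_nM"].to_numpy(), df["beta"].to_numpy())

    def fit(self, n_starts: int = 8, seed: int = 0) -> FitResult:
        ahl, beta = self.ahl, self.beta
        bmax = float(beta.max())
        if bmax <= 0:
            raise EstimationError("all beta estimates are zero")

        def resid(theta):
            b0, logk, m = theta
            k = 10.0 ** logk
            pred = b0 * np.where(ahl > 0, hill(ahl, k, max(m, 1.0)), 0.0)
            return pred - beta

        pos = ahl[ahl > 0]
        lo = np.array([1e-9, math.log10(pos.min()) - 2, 1.0])
        hi = np.array([10 * bmax, math.log10(pos.max()) + 2, 10.0])
        rng = np.random.default_rng(seed)
        sampler = qmc.LatinHypercube(d=3, seed=rng)
        starts = lo + sampler.random(n_starts) * (hi - lo)
        starts[0] = [bmax, math.log10(np.median(pos)), 1.5]

        best, ssrs = None, []
        for x0 in starts:
            try:
                res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            ssrs.append(2 * res.cost)
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise EstimationError("Hill fit failed from every start")
        b0, logk, m = best.x
        k = 10.0 ** logk
        ssr = float(2 * best.cost)
        cov = _gn_cov(best.jac, ssr, len(beta))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        bse = {"beta0": float(se[0]), "k": float(se[1] * k * math.log(10)),
               "m": float(se[2])}
        return FitResult(
            params={"beta0": float(b0), "k": float(k), "m": float(m)},
            bse=bse, ssr=ssr, nobs=len(beta), converged=bool(best.success),
            restart_ssr=np.array(ssrs),
        )


# ---------------------------------------------------------------------------
# Full growth-curve fit
# ---------------------------------------------------------------------------

#: Parameters a growth-curve fit may free, with (lower, upper) bounds.
GROWTH_BOUNDS = {
    "gamma0": (1e-3, 5.0),
    "rho_s": (1e-3, 2.0),
    "alpha0": (1e-3, 10.0),
    "K": (1e-3, 20.0),
    "n": (1.0, 10.0),
    "x0": (1e-12, 1.0),
    "y0": (1e-12, 1.0),
}
_LOG_PARAMS = {"x0", "y0"}  # optimised on a log10 scale


def _as_dataframe(data) -> pd.DataFrame:
    if isinstance(data, GrowthCurveSet):
        return data.data
    return data


class GrowthCurveModel:
    """Joint fit of the lysis-circuit model to plate-reader growth curves.

    Minimises the summed squared residuals between observed density and
    simulated total density x + y across all conditions simultaneously, with
    parameters shared between conditions and the inducer level taken from
    each condition.  Replicates are fitted jointly (stacked residuals), not
    averaged.  The objective is multi-modal in (K, n), hence bounded local
    least squares from Latin-hypercube multi-starts.

    Parameters
    ----------
    data : GrowthCurveSet or DataFrame
        Blank-subtracted densities in the canonical tidy format.
    fixed : ModelParams
        Values for every model parameter; entries named in ``free`` are used
        only to complete the simulation and are replaced by estimates.
    free : sequence of str
        Subset of {gamma0, rho_s, alpha0, K, n, x0, y0}.  The induction Hill
        (beta0, k, m) is always fixed: it is calibrated independently.
    x0, y0 : float
        Initial densities (shared across conditions) when not freed.
    loss : {"linear", "log"}
        Residuals on density (default) or on log1p-density, which balances
        the post-crash regime.
    """

    def __init__(self, data, fixed: ModelParams,
                 free: Sequence[str] = ("gamma0", "rho_s", "alpha0", "K", "n"),
                 x0: float = 0.01, y0: float = 1e-6,
                 dt: float = 1e-3, positive_part: str = "net_growth",
                 loss: str = "linear"):
        df = _as_dataframe(data)
        self._df = df
        self.free = tuple(free)
        bad = set(self.free) - set(GROWTH_BOUNDS)
        if bad:
            raise ValueError(f"cannot free parameters {sorted(bad)}")
        if loss not in ("linear", "log"):
            raise ValueError("loss must be 'linear' or 'log'")
        self.fixed = fixed
        self.x0, self.y0 = float(x0), float(y0)
        self.dt = float(dt)
        self.loss = loss
        self.pp_mode = {"net_growth": 0, "growth": 1}[positive_part]

        self._conditions = []
        nobs = 0
        for cond, g in df.groupby("condition"):
            ahl = float(g["ahl_nM"].iloc[0])
            t = g["time_h"].to_numpy(dtype=float)
            od = g["od600"].to_numpy(dtype=float)
            if np.unique(t).size < 2:
                raise EstimationError(
                    f"condition {cond!r} has a single time point; cannot fit dynamics"
                )
            self._conditions.append((cond, ahl, t, od))
            nobs += len(t)
        if not self._conditions:
            raise EstimationError("empty growth-curve table")
        self.nobs = nobs
        if nobs <= len(self.free):
            raise EstimationError("fewer observations than free parameters")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fixed: ModelParams, **kw):
        return cls(df, fixed, **kw)

    # -- parameter transforms ------------------------------------------------

    def _pack(self, values: Dict[str, float]) -> np.ndarray:
        out = []
        for name in self.free:
            v = values[name]
            out.append(math.log10(v) if name in _LOG_PARAMS else v)
        return np.array(out)

    def _unpack(self, theta: np.ndarray) -> Dict[str, float]:
        out = {}
        for name, v in zip(self.free, theta):
            out[name] = 10.0 ** v if name in _LOG_PARAMS else float(v)
        return out

    def _bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free:
            a, b = GROWTH_BOUNDS[name]
            if name in _LOG_PARAMS:
                a, b = math.log10(a), math.log10(b)
            lo.append(a)
            hi.append(b)
        return np.array(lo), np.array(hi)

    # -- simulation ----------------------------------------------------------

    def _simulate_condition(self, p: ModelParams, x0: float, y0: float,
                            ahl: float, t_grid_end: float) -> Tuple[np.ndarray, np.ndarray]:
        n_steps = int(math.ceil(t_grid_end / self.dt)) + 1
        levels = np.full(n_steps, ahl)
        x, y, pp, _, _, _, bad = euler_run(
            x0, y0, 0.0, 1.0, 0.0, levels, self.dt,
            p.gamma0, p.rho_s, p.alpha0, p.K, p.n, p.beta0, p.k, p.m, p.delta,
            0.0, 0.0, 0.0, 0.0, 0, self.pp_mode,
        )
        if bad >= 0:
            raise EstimationError(f"simulation diverged during fit at step {bad}")
        times = self.dt * np.arange(n_steps + 1)
        return times, x + y

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        est = self._unpack(theta)
        p = self.fixed.replace(**{k: v for k, v in est.items()
                                  if k not in ("x0", "y0")})
        x0 = est.get("x0", self.x0)
        y0 = est.get("y0", self.y0)
        out = []
        for _, ahl, t, od in self._conditions:
            times, tot = self._simulate_condition(p, x0, y0, ahl, t.max())
            pred = np.interp(t, times, tot)
            if self.loss == "log":
                out.append(np.log1p(pred) - np.log1p(od))
            else:
                out.append(pred - od)
        return np.concatenate(out)

    # -- fitting -------------------------------------------------------------

    def fit(self, n_starts: int = 16, seed: int = 0,
            init_guess: Optional[Dict[str, float]] = None) -> FitResult:
        """Bounded least squares from Latin-hypercube multi-starts.

        ``init_guess`` (free-parameter name -> value) replaces the first
        start; the remaining starts explore the bounds.
        """
        lo, hi = self._bounds()
        rng = np.random.default_rng(seed)
        starts = []
        if init_guess is not None:
            full = {name: init_guess.get(
                name,
                getattr(self.fixed, name, None) if name not in ("x0", "y0")
                else {"x0": self.x0, "y0": self.y0}[name],
            ) for name in self.free}
            starts.append(np.clip(self._pack(full), lo, hi))
        n_lhs = max(n_starts - len(starts), 0)
        if n_lhs:
            sampler = qmc.LatinHypercube(d=len(self.free), seed=rng)
            starts.extend(lo + sampler.random(n_lhs) * (hi - lo))

        best, ssrs = None, []
        for s in starts:
            try:
                res = optimize.least_squares(
                    self._residuals, s, bounds=(lo, hi), method="trf",
                    xtol=1e-10, ftol=1e-10,
                )
            except EstimationError:
                continue
            ssrs.append(2 * res.cost)
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise EstimationError("growth-curve fit failed from every start")

        est = self._unpack(best.x)
        ssr = float(2 * best.cost)
        cov = _gn_cov(best.jac, ssr, self.nobs)
        se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
        bse = {}
        for i, name in enumerate(self.free):
            if name in _LOG_PARAMS:  # delta method through 10**theta
                bse[name] = float(se_t[i] * est[name] * math.log(10))
            else:
                bse[name] = float(se_t[i])
        fixed_rec = {k: v for k, v in self.fixed.to_dict().items()
                     if k not in self.free}
        if "x0" not in self.free:
            fixed_rec["x0"] = self.x0
        if "y0" not in self.free:
            fixed_rec["y0"] = self.y0
        return FitResult(params=est, bse=bse, ssr=ssr, nobs=self.nobs,
                         converged=bool(best.success), fixed=fixed_rec,
                         restart_ssr=np.array(ssrs))

    def bootstrap(self, n_boot: int = 20, seed: int = 0,
                  n_starts: int = 2) -> Dict[str, np.ndarray]:
        """Bootstrap-over-replicates parameter distributions.

        Resamples replicates with replacement within each condition, refits,
        and returns the array of estimates per free parameter.  A sturdier
        alternative to the Gauss-Newton covariance when (K, n) are strongly
        correlated; point estimates should come from :meth:`fit`.
        """
        rng = np.random.default_rng(seed)
        base = self.fit(n_starts=max(n_starts, 2), seed=seed)
        draws = {name: [] for name in self.free}
        for b in range(n_boot):
            parts = []
            for cond, g in self._df.groupby("condition"):
                reps = g["replicate"].unique()
                pick = rng.choice(reps, size=len(reps), replace=True)
                for new_id, rep in enumerate(pick):
                    sub = g[g["replicate"] == rep].copy()
                    sub["replicate"] = new_id
                    parts.append(sub)
            resampled = pd.concat(parts, ignore_index=True)
            model = GrowthCurveModel(resampled, self.fixed, free=self.free,
                                     x0=self.x0, y0=self.y0, dt=self.dt,
                                     loss=self.loss)
            model.pp_mode = self.pp_mode
            try:
                res = model.fit(n_starts=n_starts, seed=seed + 1 + b,
                                init_guess=dict(base.params))
            except EstimationError:
                continue
            for name in self.free:
                draws[name].append(res.params[name])
        return {name: np.asarray(v) for name, v in draws.items()}


# ---------------------------------------------------------------------------
# Mutant-fraction estimation from a single-condition curve
# ---------------------------------------------------------------------------

@dataclass
class MutantFractionEstimate:
    """Initial composition of a culture read off its induced growth curve."""

    x0: float
    y0: float
    f0: float
    f0_sd: float
    per_replicate_f0: Dict = field(default_factory=dict)
    flagged: bool = False
    message: str = ""
    fit: Optional[FitResult] = None

    def summary(self) -> str:
        lines = [
            "MutantFractionEstimate",
            f"  x0 = {self.x0:.4g}  y0 = {self.y0:.4g}",
            f"  f0 = {self.f0:.4g} +/- {self.f0_sd:.2g}",
        ]
        if self.per_replicate_f0:
            reps = ", ".join(f"{k}: {v:.3g}" for k, v in self.per_replicate_f0.items())
            lines.append(f"  per-replicate f0: {reps}")
        if self.flagged:
            lines.append(f"  FLAGGED: {self.message}")
        return "\n".join(lines)


class MutantFractionModel:
    """Estimate the initial mutant fraction of a culture from its growth curve.

    All rate parameters are held fixed (they characterise the strain); only
    the initial densities x0 and y0 are fitted, so the post-crash regrowth
    timing identifies y0 and the pre-crash curve identifies x0.  Data must be
    a single inducer condition (the protocol refreshes to density 0.01 under
    100 nM induction); triplicates are fitted jointly, and the dispersion of
    per-replicate refits gives the f0 uncertainty.
    """

    def __init__(self, data, fixed: ModelParams, dt: float = 1e-3,
                 positive_part: str = "net_growth"):
        df = _as_dataframe(data)
        levels = df["ahl_nM"].unique()
        if len(levels) != 1:
            raise EstimationError(
                "mutant-fraction protocol expects a single inducer condition"
            )
        self.df = df
        self.fixed = fixed
        self.dt = dt
        self.positive_part = positive_part

    def _joint_fit(self, df: pd.DataFrame, seed: int) -> FitResult:
        df = df.copy()
        df["condition"] = "pooled"
        gcm = GrowthCurveModel(df, self.fixed, free=("x0", "y0"),
                               dt=self.dt, positive_part=self.positive_part)
        return gcm.fit(n_starts=8, seed=seed)

    def fit(self, seed: int = 0) -> MutantFractionEstimate:
        res = self._joint_fit(self.df, seed)
        x0, y0 = res.params["x0"], res.params["y0"]
        f0 = y0 / (x0 + y0)

        per_rep = {}
        for rep, g in self.df.groupby("replicate"):
            try:
                r = self._joint_fit(g, seed)
                per_rep[rep] = r.params["y0"] / (r.params["x0"] + r.params["y0"])
            except EstimationError:
                continue
        f0_sd = float(np.std(list(per_rep.values()), ddof=1)) if len(per_rep) > 1 else 0.0

        flagged, message = False, ""
        lo_y0 = GROWTH_BOUNDS["y0"][0]
        if y0 <= 10 * lo_y0:
            flagged = True
            message = "y0 estimate at its lower bound; no mutant signal in the curve"
        elif not self._has_regrowth(res):
            flagged = True
            message = ("curve lacks the post-crash regrowth signature; "
                       "y0 is weakly determined")
        return MutantFractionEstimate(x0=x0, y0=y0, f0=f0, f0_sd=f0_sd,
                                      per_replicate_f0=per_rep, flagged=flagged,
                                      message=message, fit=res)

    def _has_regrowth(self, res: FitResult) -> bool:
        # pooled-mean observed curve: look for fall then rise after the peak
        g = self.df.groupby("time_h")["od600"].mean()
        od = g.to_numpy()
        if od.size < 7:
            return False
        kernel = np.ones(5) / 5.0
        sm = np.convolve(od, kernel, mode="valid")
        d = np.diff(sm)
        signs = np.sign(d[np.abs(d) > 1e-12])
        changes = int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
        return changes >= 2


# ---------------------------------------------------------------------------
# f(t_ind) fit — linear on the logit scale
# ---------------------------------------------------------------------------

class FractionInductionModel:
    """Fit the constant-lysis-rate mutant-fraction law to f(t_ind) points.

    The law f(t) = e^{alpha t} / (1/f0 - 1 + e^{alpha t}) is exactly linear on
    the logit scale: logit f = logit f0 + alpha t.  The fit is therefore
    ordinary least squares of logit(f) on t, returning the lysis rate alpha
    (slope) and the stock mutant fraction f0 (inverse-logit intercept) with
    Gaussian standard errors and t-based confidence intervals.
    """

    def __init__(self, t_ind: Sequence[float], f_estimates: Sequence[float]):
        t = np.asarray(list(t_ind), dtype=float)
        f = np.asarray(list(f_estimates), dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("t_ind and f_estimates must be aligned 1-D sequences")
        if t.size < 3:
            raise EstimationError("need >= 3 induction times")
        if np.any((f <= 0) | (f >= 1)):
            raise EstimationError("fractions must lie strictly inside (0, 1)")
        if np.allclose(f, f[0]):
            raise EstimationError("all fractions identical; alpha is unidentified")
        if np.allclose(t, t[0]):
            raise EstimationError("all induction times identical")
        self.t = t
        self.f = f

    def fit(self) -> FitResult:
        t, f = self.t, self.f
        z = np.log(f / (1.0 - f))
        X = np.column_stack([np.ones_like(t), t])
        coef, res_ss, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ coef
        ssr = float(resid @ resid)
        dof = len(t) - 2
        s2 = ssr / dof if dof > 0 else float("nan")
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        intercept, slope = coef
        f0 = 1.0 / (1.0 + math.exp(-intercept))
        # delta method: df0/d(intercept) = f0 (1 - f0)
        f0_se = se[0] * f0 * (1.0 - f0)
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
        result = FitResult(
            params={"alpha": float(slope), "f0": float(f0)},
            bse={"alpha": float(se[1]), "f0": float(f0_se)},
            ssr=ssr, nobs=len(t), converged=True,
        )
        result.conf_int = {
            "alpha": (float(slope - tcrit * se[1]), float(slope + tcrit * se[1])),
            "logit_f0": (float(intercept - tcrit * se[0]),
                         float(intercept + tcrit * se[0])),
        }
        result.logit_intercept = float(intercept)
        result.logit_intercept_se = float(se[0])
        return result
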