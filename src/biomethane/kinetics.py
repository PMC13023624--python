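"""Kinetic models for cumulative methane production and substrate hydrolysis.

Four closed-form models B(t) are fitted to specific cumulative methane curves
(mL CH4 per g VS):

* modified Gompertz:  B = B0 * exp(-exp(Rmax * e / B0 * (lambda - t) + 1))
* logistic:           B = B0 / (1 + exp(4 * Rmax / B0 * (lambda - t) + 2))
* Cone:               B = B0 / (1 + (k t)^(-n)),  B(0) = 0 by continuity
* first-order:        B = B0 * (1 - exp(-k t))

with B0 the ultimate yield (mL/g VS), Rmax the maximum production rate
(mL/g VS/d), lambda the lag phase (d), k a rate constant (1/d) and n the
Cone shape factor.  Substrate disappearance is described by first-order
hydrolysis S(t) = S0 * exp(-k_deg * t).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .gas_preprocess import YieldCurve

E = np.e

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "modified_gompertz": ("B0", "Rmax", "lambda_"),
    "logistic": ("B0", "Rmax", "lambda_"),
    "cone": ("B0", "k", "n_shape"),
    "first_order": ("B0", "k"),
}

MODEL_NAMES = tuple(MODEL_PARAMS)


@dataclass
class KineticModelSpec:
    """A named kinetic model with its parameter values."""

    name: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in MODEL_PARAMS:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        expected = set(MODEL_PARAMS[self.name])
        if set(self.params) != expected:
            raise ValueError(f"{self.name} expects parameters {sorted(expected)}")
        if self.params["B0"] <= 0:
            raise ValueError("B0 must be > 0")
        lam = self.params.get("lambda_")
        if lam is not None and lam < 0:
            raise ValueError("lambda must be >= 0")
        for p in ("Rmax", "k", "n_shape"):
            if p in self.params and self.params[p] <= 0:
                raise ValueError(f"{p} must be > 0")


@dataclass
class KineticFit:
    spec: KineticModelSpec
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    ss_res: float = field(default=np.nan)


@dataclass
class HydrolysisFit:
    s0: float
    k_deg: float
    r_squared: float


def _clip_exp(x: np.ndarray) -> np.ndarray:
    # exp argument clamp: avoids overflow warnings during multi-start search
    return np.exp(np.clip(x, -700.0, 700.0))


def model_curve(spec: KineticModelSpec, times) -> np.ndarray:
    """Evaluate a kinetic model at the given times (days, >= 0)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    p = spec.params
    b0 = p["B0"]
    if spec.name == "modified_gompertz":
        return b0 * _clip_exp(-_clip_exp(p["Rmax"] * E / b0 * (p["lambda_"] - t) + 1.0))
    if spec.name == "logistic":
        return b0 / (1.0 + _clip_exp(4.0 * p["Rmax"] / b0 * (p["lambda_"] - t) + 2.0))
    if spec.name == "cone":
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = b0 / (1.0 + (p["k"] * t[pos]) ** (-p["n_shape"]))
        return out
    # first_order
    return b0 * (1.0 - _clip_exp(-p["k"] * t))


def _initial_guesses(times: np.ndarray, cum: np.ndarray, names: tuple[str, ...]):
    final = cum[-1]
    inc = np.diff(cum)
    dt = np.diff(times)
    rmax0 = float(np.max(inc / np.maximum(dt, 1e-9))) if inc.size else final
    above = times[cum > 0.01 * final]
    lam0 = float(above[0]) if above.size else 0.0
    base = {"B0": max(final, 1e-9), "Rmax": max(rmax0, 1e-9), "lambda_": max(lam0, 1e-3), "k": 0.5, "n_shape": 2.0}
    # small multiplicative grid around each heuristic start
    factors = [0.5, 1.0, 2.0]
    starts = []
    for combo in itertools.product(factors, repeat=len(names)):
        starts.append(np.array([base[nm] * f for nm, f in zip(names, combo)]))
    return starts


def _bounds(times: np.ndarray, cum: np.ndarray, names: tuple[str, ...]):
    duration = float(times[-1])
    final = float(cum[-1])
    lo, hi = [], []
    for nm in names:
        if nm == "B0":
            lo.append(1e-9)
            hi.append(3.0 * final)
        elif nm == "lambda_":
            lo.append(0.0)
            hi.append(duration)
        else:
            lo.append(1e-9)
            hi.append(np.inf)
    return np.array(lo), np.array(hi)


def fit_kinetic(curve: YieldCurve, model: str) -> KineticFit:
    """Nonlinear least-squares fit of one model to a cumulative yield curve.

    Multi-start Levenberg-style trust-region fitting from a grid of scaled
    heuristic initial values; the best start by residual sum of squares wins.
    R^2 = 1 - SS_res / SS_tot on the fitted curve.  Non-convergence of every
    start is reported honestly through ``converged=False``.
    """
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    names = MODEL_PARAMS[model]
    times = curve.times
    cum = curve.cumulative
    if len(times) < 2 + len(names):
        raise ValueError("too few points to fit")
    if cum[-1] <= 0:
        raise ValueError("no fittable signal: final cumulative production is zero")

    lo, hi = _bounds(times, cum, names)

    def resid(theta):
        spec = KineticModelSpec(model, dict(zip(names, theta)))
        return model_curve(spec, times) - cum

    best = None
    any_ok = False
    for x0 in _initial_guesses(times, cum, names):
        x0 = np.clip(x0, lo, np.where(np.isfinite(hi), hi, x0))
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:  # pragma: no cover - defensive
            continue
        any_ok = any_ok or sol.success
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[0]:
            best = (ss, sol)
    if best is None:
        raise RuntimeError(f"all starts failed for model {model}")
    ss_res, sol = best
    spec = KineticModelSpec(model, dict(zip(names, map(float, sol.x))))
    ss_tot = float(np.sum((cum - cum.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return KineticFit(
        spec=spec,
        r_squared=float(r2),
        residuals=np.asarray(sol.fun),
        converged=bool(any_ok),
        n_points=len(times),
        ss_res=ss_res,
    )


def fit_all_models(curve: YieldCurve, models=MODEL_NAMES) -> pd.DataFrame:
    """Fit every model; one report row per model, failures isolated.

    Columns mirror the conventional BMP kinetics table: B0 (mL/g VS),
    Rmax (mL/g VS/d), lambda (d), k (1/d), n (-), R2 (%).  Parameters a model
    does not define are left as NaN; R2 is reported in percent.
    """
    rows = []
    for m in models:
        row: dict[str, float | str | bool] = {"model": m, "B0": np.nan, "Rmax": np.nan,
                                              "lambda": np.nan, "k": np.nan, "n": np.nan,
                                              "R2_pct": np.nan, "converged": False}
        try:
            fit = fit_kinetic(curve, m)
        except Exception as exc:
            warnings.warn(f"fit of {m} failed: {exc}", stacklevel=2)
            rows.append(row)
            continue
        p = fit.spec.params
        row.update(
            B0=p["B0"],
            Rmax=p.get("Rmax", np.nan),
            **{"lambda": p.get("lambda_", np.nan)},
            k=p.get("k", np.nan),
            n=p.get("n_shape", np.nan),
            R2_pct=round(100.0 * fit.r_squared, 2),
            converged=fit.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def hydrolysis_k_single_point(removal_fraction: float, t: float) -> float:
    """First-order hydrolysis rate constant from a single removal measurement.

    Inverts S_t = S0 * exp(-k_deg t):  k_deg = -ln(1 - removal) / t  (1/d).
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError("removal_fraction must lie in [0, 1); 1 implies an infinite rate")
    if t <= 0:
        raise ValueError("t must be > 0")
    return float(-np.log1p(-removal_fraction) / t)


def fit_hydrolysis(times, concentrations, method: str = "nls") -> HydrolysisFit:
    """Fit S(t) = S0 * exp(-k_deg t) to a substrate-concentration series.

    ``method='nls'`` (default) fits on the original scale; ``'log-linear'``
    regresses ln S on t.  Non-positive concentrations are excluded with a
    warning (the log transform cannot see them and NLS treats them as outliers
    of an always-positive model).
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(concentrations, dtype=float)
    if t.shape != s.shape or t.size < 3:
        raise ValueError("need >= 3 matching (time, concentration) points")
    keep = s > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} non-positive concentration(s)", stacklevel=2)
        t, s = t[keep], s[keep]
    if t.size < 3 or s[0] <= 0:
        raise ValueError("too few positive points after exclusion")

    if method == "log-linear":
        slope, intercept = np.polyfit(t, np.log(s), 1)
        s0, k = float(np.exp(intercept)), float(max(-slope, 0.0))
    elif method == "nls":
        # log-linear start, then NLS on the original scale
        slope, intercept = np.polyfit(t, np.log(s), 1)
        x0 = np.array([np.exp(intercept), max(-slope, 1e-9)])
        sol = least_squares(
            lambda th: th[0] * np.exp(-th[1] * t) - s,
            x0, bounds=([1e-12, 0.0], [np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        s0, k = float(sol.x[0]), float(sol.x[1])
        # boundary candidate: a non-decaying series is fit best by k = 0
        ss_nls = float(np.sum((s0 * np.exp(-k * t) - s) ** 2))
        ss_k0 = float(np.sum((s.mean() - s) ** 2))
        if ss_k0 <= ss_nls:
            s0, k = float(s.mean()), 0.0
    else:
        raise ValueError("method must be 'nls' or 'log-linear'")

    pred = s0 * np.exp(-k * t)
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    ss_res = float(np.sum((s - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HydrolysisFit(s0=s0, k_deg=k, r_squared=r2)
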