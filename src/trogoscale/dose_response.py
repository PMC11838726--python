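"""Sigmoid dose-response fitting and critical-density extraction.

Trogocytic efficiency versus antibody surface density is fit with a logistic

    y = a / (1 + exp(-(x - rho_crit) / d))

whose inflection point ``rho_crit`` is the critical antibody density.  The
equivalent decreasing parameterisation ``y = a * (1 - 1/(1+exp(-(x-rho)/d)))``
is available as ``form="decreasing"``; it describes the identical curve under
``d -> -d`` and has the same inflection point.  Uncertainty comes from a
case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "SigmoidFit",
    "BootstrapInterval",
    "TensionScalingFit",
    "fit_sigmoid",
    "sigmoid_predict",
    "bootstrap_rho_crit",
    "rho_crit_vs_tension",
]

_FORMS = ("increasing", "decreasing")


@dataclass(frozen=True)
class SigmoidFit:
    a: float                 # plateau, %
    rho_crit: float          # antibodies/um^2 (inflection point)
    d: float                 # width, antibodies/um^2 (sign carries direction)
    rss: float               # squared-% units
    converged: bool
    form: str = "increasing"
    log_x: bool = False
    n_points: int = 0
    rho_crit_ci: Optional[Tuple[float, float]] = None


@dataclass(frozen=True)
class BootstrapInterval:
    lo: float
    hi: float
    n_boot: int
    n_converged: int
    unreliable: bool
    samples: np.ndarray


@dataclass(frozen=True)
class TensionScalingFit:
    """OLS of rho_crit on tension with bootstrap uncertainty."""

    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    n: int
    boot_slopes: np.ndarray
    boot_intercepts: np.ndarray

    def band(self, x: Sequence[float], level: float = 0.95) -> pd.DataFrame:
        """Pointwise percentile envelope of the bootstrapped fitted line."""
        x = np.asarray(x, dtype=float)
        lines = self.boot_slopes[:, None] * x[None, :] + self.boot_intercepts[:, None]
        alpha = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(lines, [alpha, 100.0 - alpha], axis=0)
        return pd.DataFrame({
            "x": x,
            "fit": self.slope * x + self.intercept,
            "lo": lo,
            "hi": hi,
        })


def _sign(form: str) -> float:
    if form not in _FORMS:
        raise ValueError(f"form must be one of {_FORMS}, got {form!r}")
    return 1.0 if form == "increasing" else -1.0


def _model(params: np.ndarray, x: np.ndarray, sign: float) -> np.ndarray:
    a, rho, d = params
    return a * expit(sign * (x - rho) / d)


def sigmoid_predict(fit: SigmoidFit, x) -> np.ndarray:
    """Evaluate a fitted curve at densities ``x`` (original units)."""
    x = np.asarray(x, dtype=float)
    if fit.log_x:
        x = np.log10(x)
        rho = np.log10(fit.rho_crit)
    else:
        rho = fit.rho_crit
    return _model(np.array([fit.a, rho, fit.d]), x, _sign(fit.form))


def _extract_xy(t, aggregate_replicates: bool) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(t, pd.DataFrame):
        if aggregate_replicates:
            t = t.groupby("density", as_index=False)["efficiency"].mean()
        x = t["density"].to_numpy(dtype=float)
        y = t["efficiency"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in t)
    return x, y


def _solve(x: np.ndarray, y: np.ndarray, p0: np.ndarray, sign: float,
           bounded: bool = True):
    fun = lambda p: _model(p, x, sign) - y
    if bounded:
        lb = np.array([1e-9, -np.inf, -np.inf])
        ub = np.array([100.0, np.inf, np.inf])
        p0 = np.clip(p0, lb + 1e-12, ub - 1e-12)
        return least_squares(fun, p0, bounds=(lb, ub), method="trf",
                             xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return least_squares(fun, p0, method="lm", xtol=1e-12, ftol=1e-12)


def fit_sigmoid(t, form: str = "increasing", log_x: bool = False,
                aggregate_replicates: bool = False) -> SigmoidFit:
    """Least-squares logistic fit with multistart initialisation.

    Accepts a dose-response table (columns ``density``, ``efficiency``) or an
    ``(x, y)`` pair.  Requires >=4 distinct densities and a non-constant
    response.  Starts span the density quartiles and both width signs; the
    best-RSS solution wins, so the returned optimum is at least as good as
    every start.  ``log_x=True`` fits against log10(density) and reports
    ``rho_crit`` back on the density scale (``d`` then in decades).
    """
    sign = _sign(form)
    x, y = _extract_xy(t, aggregate_replicates)
    if x.size != y.size or x.size == 0:
        raise ValueError("density and efficiency must be equal-length and non-empty")
    if np.unique(x).size < 4:
        raise ValueError("need >=4 distinct densities to fit a sigmoid")
    if np.allclose(y, y[0]):
        raise ValueError("efficiency is constant: no transition to fit")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log_x requires strictly positive densities")
        x = np.log10(x)

    span = float(x.max() - x.min())
    a0 = float(np.clip(y.max(), 1.0, 100.0))
    starts = [np.array([a0, r0, s * span / 5.0])
              for r0 in np.percentile(x, [25, 50, 75])
              for s in (sign, -sign)]
    best = None
    for p0 in starts:
        try:
            res = _solve(x, y, p0, sign)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return SigmoidFit(a=np.nan, rho_crit=np.nan, d=np.nan, rss=np.nan,
                          converged=False, form=form, log_x=log_x, n_points=x.size)
    a, rho, d = best.x
    rss = float(2.0 * best.cost)
    rho_out = float(10 ** rho) if log_x else float(rho)
    converged = bool(best.success and np.all(np.isfinite(best.x))
                     and a > 0 and d != 0 and rho_out > 0)
    return SigmoidFit(a=float(a), rho_crit=rho_out, d=float(d), rss=rss,
                      converged=converged, form=form, log_x=log_x,
                      n_points=int(x.size))


def _refit_rho(x: np.ndarray, y: np.ndarray, p0: np.ndarray,
               sign: float) -> float:
    """Fast unbounded refit from a warm start; NaN when degenerate."""
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = _solve(x, y, p0, sign, bounded=False)
    except Exception:
        return np.nan
    a, rho, d = res.x
    if not (res.status > 0 and np.all(np.isfinite(res.x)) and 0 < a <= 150 and d != 0):
        return np.nan
    return float(rho)


def bootstrap_rho_crit(t, n_boot: int = 2000, seed: int = 0,
                       form: str = "increasing",
                       base_fit: Optional[SigmoidFit] = None,
                       aggregate_replicates: bool = False) -> BootstrapInterval:
    """95% percentile interval for the inflection point by case resampling.

    Rows of (density, efficiency) are resampled with replacement and the
    sigmoid refit from the full-data optimum.  The interval is flagged
    unreliable when more than 20% of bootstrap fits fail.
    """
    sign = _sign(form)
    x, y = _extract_xy(t, aggregate_replicates)
    if base_fit is None:
        base_fit = fit_sigmoid((x, y), form=form)
    if not base_fit.converged:
        raise ValueError("base sigmoid fit did not converge; cannot bootstrap")
    rho0 = np.log10(base_fit.rho_crit) if base_fit.log_x else base_fit.rho_crit
    p0 = np.array([base_fit.a, rho0, base_fit.d])
    rng = np.random.default_rng(seed)
    n = x.size
    samples = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        samples[b] = _refit_rho(x[idx], y[idx], p0, sign)
    ok = samples[np.isfinite(samples)]
    n_conv = int(ok.size)
    unreliable = n_conv < 0.8 * n_boot
    if n_conv == 0:
        return BootstrapInterval(np.nan, np.nan, n_boot, 0, True, samples)
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return BootstrapInterval(float(lo), float(hi), n_boot, n_conv, unreliable, ok)


def rho_crit_vs_tension(tensions: Sequence[float], rho_crits: Sequence[float],
                        n_boot: int = 2000, seed: int = 0) -> TensionScalingFit:
    """OLS of critical density on tension with a case-resampling bootstrap
    confidence band (percentile, default 2000 draws)."""
    x = np.asarray(tensions, dtype=float)
    y = np.asarray(rho_crits, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >=2 (tension, rho_crit) pairs")
    if np.unique(x).size < 2:
        raise ValueError("tensions are all identical: slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    filled = 0
    attempts = 0
    while filled < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, x.size, size=x.size)
        if np.unique(x[idx]).size < 2:
            continue            # degenerate resample: line undefined
        s, i = np.polyfit(x[idx], y[idx], 1)
        slopes[filled] = s
        intercepts[filled] = i
        filled += 1
    slopes = slopes[:filled]
    intercepts = intercepts[:filled]
    slope_ci = tuple(np.percentile(slopes, [2.5, 97.5]))
    intercept_ci = tuple(np.percentile(intercepts, [2.5, 97.5]))
    return TensionScalingFit(
        slope=float(slope), intercept=float(intercept),
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept_ci=(float(intercept_ci[0]), float(intercept_ci[1])),
        n=int(x.size), boot_slopes=slopes, boot_intercepts=intercepts,
    )
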