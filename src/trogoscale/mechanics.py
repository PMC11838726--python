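"""Interfacial force-balance scaling model for the trogocytosis/phagocytosis decision.

The minimum scale of target-membrane deformation is set by balancing the
antibody-scaled active normal stress against the target surface tension::

    R_min = gamma / sigma_eff(rho)          sigma_eff(rho) = sigma_ref * rho / rho_ref

Bites smaller than the macrophage-target interface (``R_min < R``) mean the
macrophage can pinch off membrane fragments (trogocytosis); otherwise it can
only engulf the whole target (phagocytosis).  Below an engagement floor
``rho_min`` neither occurs.  All proportionality constants are fixed at 1 —
this is a scaling law, accurate to order of magnitude.

Unit conventions at the interface: tensions in mN/m, lengths in um,
stresses in Pa, bending stiffness in J.  Conversions to SI happen internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MechanicalParams",
    "ScalingPrediction",
    "BiteSizeComparison",
    "effective_stress",
    "r_min",
    "l_bend",
    "classify_regime",
    "critical_density",
    "critical_tension",
    "phase_diagram",
    "boundary_curves",
    "compare_bite_sizes",
    "calibrate_to_switch_tension",
]

_MN_PER_M_TO_N_PER_M = 1e-3
_M_TO_UM = 1e6
_UM_TO_M = 1e-6

NO_ENGAGEMENT = "no_engagement"
TROGOCYTOSIS = "trogocytosis"
PHAGOCYTOSIS = "phagocytosis"


@dataclass(frozen=True)
class MechanicalParams:
    """Calibration of the scaling model.

    Parameters
    ----------
    sigma_ref : float
        Active normal stress (Pa) exerted at the reference antibody density.
    rho_ref : float
        Reference antibody density (antibodies/um^2) at which ``sigma_ref``
        applies.  Stress is assumed linear in density.
    interface_radius : float
        Macrophage-target interface size R in um.
    bending_stiffness : float
        Membrane bending modulus kappa in J.
    rho_min : float
        Engagement floor (antibodies/um^2); below it no interaction occurs.
    """

    sigma_ref: float = 100.0
    rho_ref: float = 400.0
    interface_radius: float = 1.0
    bending_stiffness: float = 1e-19
    rho_min: float = 100.0

    def __post_init__(self) -> None:
        for name in ("sigma_ref", "rho_ref", "interface_radius",
                     "bending_stiffness", "rho_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MechanicalParams.{name} must be positive")


@dataclass(frozen=True)
class ScalingPrediction:
    """Model output at a single (tension, density) point."""

    gamma: float            # mN/m
    rho: float              # antibodies/um^2
    r_min: float            # um
    l_bend: float           # um
    regime: str


@dataclass(frozen=True)
class BiteSizeComparison:
    geometric_mean_measured: float   # um
    predicted_r_min: float           # um
    ratio: float                     # measured / predicted
    within_order_of_magnitude: bool
    n: int


def effective_stress(rho, p: MechanicalParams):
    """Active normal stress (Pa) at antibody density ``rho``, linear in rho."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    out = p.sigma_ref * rho / p.rho_ref
    return float(out) if out.ndim == 0 else out


def r_min(gamma, rho, p: MechanicalParams):
    """Minimum deformation (bite) scale in um.

    ``R_min = gamma / sigma_eff``; zero density gives an infinite sentinel
    (no active stress, nothing to deform the interface).
    """
    gamma = np.asarray(gamma, dtype=float)
    rho = np.asarray(rho, dtype=float)
    sigma = effective_stress(rho, p)
    with np.errstate(divide="ignore"):
        out = np.where(
            np.asarray(sigma) > 0,
            gamma * _MN_PER_M_TO_N_PER_M / np.where(np.asarray(sigma) > 0, sigma, 1.0) * _M_TO_UM,
            np.inf,
        )
    return float(out) if out.ndim == 0 else out


def l_bend(rho, p: MechanicalParams):
    """Bending-limited deformation scale in um: (kappa / sigma_eff)^(1/3)."""
    sigma = np.asarray(effective_stress(rho, p), dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(sigma > 0,
                       np.cbrt(p.bending_stiffness / np.where(sigma > 0, sigma, 1.0)) * _M_TO_UM,
                       np.inf)
    return float(out) if out.ndim == 0 else out


def classify_regime(gamma: float, rho: float, p: MechanicalParams) -> str:
    """Regime at a single point.

    ``no_engagement`` if rho < rho_min; else ``trogocytosis`` when
    R_min < interface_radius (strict; the boundary itself is phagocytosis),
    else ``phagocytosis``.
    """
    if rho < p.rho_min:
        return NO_ENGAGEMENT
    if r_min(gamma, rho, p) < p.interface_radius:
        return TROGOCYTOSIS
    return PHAGOCYTOSIS


def critical_density(gamma, p: MechanicalParams):
    """Density (antibodies/um^2) at which R_min equals the interface size.

    Linear in gamma through the origin: rho_crit = rho_ref * gamma_SI /
    (sigma_ref * R_SI).  Above it (at fixed gamma) trogocytosis; below it
    phagocytosis, until the rho_min floor.
    """
    gamma = np.asarray(gamma, dtype=float)
    out = (p.rho_ref * gamma * _MN_PER_M_TO_N_PER_M
           / (p.sigma_ref * p.interface_radius * _UM_TO_M))
    return float(out) if out.ndim == 0 else out


def critical_tension(rho, p: MechanicalParams):
    """Tension (mN/m) at which R_min equals the interface size; inverse of
    :func:`critical_density`."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    sigma = effective_stress(rho, p)
    out = np.asarray(sigma) * p.interface_radius * _UM_TO_M / _MN_PER_M_TO_N_PER_M
    return float(out) if out.ndim == 0 else out


def predict(gamma: float, rho: float, p: MechanicalParams) -> ScalingPrediction:
    """Full model evaluation at a single (tension, density) point."""
    return ScalingPrediction(
        gamma=float(gamma),
        rho=float(rho),
        r_min=r_min(gamma, rho, p),
        l_bend=l_bend(rho, p),
        regime=classify_regime(gamma, rho, p),
    )


def phase_diagram(gamma_grid: Sequence[float], rho_grid: Sequence[float],
                  p: MechanicalParams) -> pd.DataFrame:
    """Classify the full outer grid; long-format table of predictions."""
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if gamma_grid.size == 0 or rho_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(gamma_grid <= 0) or np.any(rho_grid <= 0):
        raise ValueError("grid values must be positive")
    gg, rr = np.meshgrid(gamma_grid, rho_grid, indexing="ij")
    gg = gg.ravel()
    rr = rr.ravel()
    rmin = r_min(gg, rr, p)
    lb = l_bend(rr, p)
    regime = np.where(rr < p.rho_min, NO_ENGAGEMENT,
                      np.where(rmin < p.interface_radius, TROGOCYTOSIS, PHAGOCYTOSIS))
    return pd.DataFrame({
        "gamma_mN_per_m": gg,
        "rho_per_um2": rr,
        "r_min_um": rmin,
        "l_bend_um": lb,
        "regime": regime,
    })


def boundary_curves(gamma_grid: Sequence[float], p: MechanicalParams) -> pd.DataFrame:
    """Analytic phase boundaries: rho_crit(gamma) and the rho_min floor."""
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    return pd.DataFrame({
        "gamma_mN_per_m": gamma_grid,
        "rho_crit_per_um2": critical_density(gamma_grid, p),
        "rho_min_per_um2": np.full_like(gamma_grid, p.rho_min),
    })


def compare_bite_sizes(measured_um: Sequence[float],
                       predicted_r_min_um: float) -> BiteSizeComparison:
    """Geometric-mean comparison of measured bite diameters to the predicted
    scale; the model is order-of-magnitude, so agreement means a ratio in
    [0.1, 10]."""
    measured = np.asarray(measured_um, dtype=float)
    if measured.size == 0:
        raise ValueError("need at least one measured bite diameter")
    if np.any(measured <= 0) or predicted_r_min_um <= 0:
        raise ValueError("diameters must be positive")
    gm = float(np.exp(np.mean(np.log(measured))))
    ratio = gm / predicted_r_min_um
    return BiteSizeComparison(
        geometric_mean_measured=gm,
        predicted_r_min=float(predicted_r_min_um),
        ratio=ratio,
        within_order_of_magnitude=bool(0.1 <= ratio <= 10.0),
        n=int(measured.size),
    )


def calibrate_to_switch_tension(gamma_switch: float, rho: float,
                                p: MechanicalParams) -> MechanicalParams:
    """Rescale ``sigma_ref`` so the critical tension at density ``rho``
    equals ``gamma_switch`` (mN/m).

    The scaling prefactor is unknown (taken as 1), so absolute regime
    boundaries depend on calibration; this pins the phase boundary to an
    observed switch tension, e.g. the ~1 mN/m vesicle threshold.
    """
    if gamma_switch <= 0 or rho <= 0:
        raise ValueError("gamma_switch and rho must be positive")
    # gamma_crit(rho) = sigma_ref*(rho/rho_ref)*R  =>  scale sigma_ref
    current = critical_tension(rho, p)
    return replace(p, sigma_ref=p.sigma_ref * gamma_switch / current)
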