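"""Antibody surface density from fluorescence via MESF calibration beads.

Beads with known fluorophore counts define a linear intensity->fluorophore
map; cell intensity is converted to IgG per cell (dividing by fluorophores
per antibody) and then to antibodies/um^2 over the spherical surface area
pi * diameter^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "DensityEstimate",
    "BelowCalibrationRangeError",
    "fit_calibration",
    "intensity_to_density",
    "density_to_intensity",
    "match_density",
]


class BelowCalibrationRangeError(ValueError):
    """Predicted fluorophore count is non-positive: intensity below the
    calibration range (or background over-subtracted)."""


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float          # fluorophores per intensity unit
    intercept: float      # fluorophores
    r_squared: float
    n_beads: int

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class DensityEstimate:
    antibodies_per_um2: float
    fluorophores_per_igg: float
    diameter: float       # um
    sample_id: str = ""


def fit_calibration(beads: pd.DataFrame) -> CalibrationCurve:
    """Unweighted OLS of MESF count on intensity over the bead table
    (columns ``intensity``, ``mesf``)."""
    for col in ("intensity", "mesf"):
        if col not in beads.columns:
            raise ValueError(f"bead table missing column {col!r}")
    x = beads["intensity"].to_numpy(dtype=float)
    y = beads["mesf"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >=2 distinct bead intensities to calibrate")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n_beads=int(x.size),
    )


def intensity_to_density(intensity: float, curve: CalibrationCurve,
                         fluorophores_per_igg: float = 6.0, diameter: float = 10.0,
                         background_intensity: float = 0.0,
                         sample_id: str = "") -> DensityEstimate:
    """Convert a cell's fluorescence intensity to antibodies/um^2.

    The default 6 fluorophores per IgG is the midpoint of the manufacturer's
    5-7 range; diameter is the cell-type average in um.  Optional background
    intensity (e.g. unstained-cell autofluorescence) is subtracted first.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if fluorophores_per_igg <= 0:
        raise ValueError("fluorophores_per_igg must be positive")
    fluorophores = curve.slope * (intensity - background_intensity) + curve.intercept
    if fluorophores <= 0:
        raise BelowCalibrationRangeError(
            f"predicted fluorophore count {fluorophores:.3g} <= 0 "
            f"(intensity {intensity:.3g} below calibration range)")
    igg = fluorophores / fluorophores_per_igg
    area = math.pi * diameter ** 2    # sphere surface area, um^2
    return DensityEstimate(
        antibodies_per_um2=igg / area,
        fluorophores_per_igg=float(fluorophores_per_igg),
        diameter=float(diameter),
        sample_id=sample_id,
    )


def density_to_intensity(density: float, curve: CalibrationCurve,
                         fluorophores_per_igg: float = 6.0,
                         diameter: float = 10.0,
                         background_intensity: float = 0.0) -> float:
    """Inverse of :func:`intensity_to_density` (round-trip helper)."""
    fluorophores = density * math.pi * diameter ** 2 * fluorophores_per_igg
    return (fluorophores - curve.intercept) / curve.slope + background_intensity


def match_density(target_density: float, measured: DensityEstimate,
                  tolerance: float = 0.25) -> bool:
    """True when the measured density lies within +-tolerance (relative) of
    the target — the surface-coverage matching check."""
    if target_density <= 0 or tolerance < 0:
        raise ValueError("target_density must be positive and tolerance >= 0")
    lo = target_density * (1.0 - tolerance)
    hi = target_density * (1.0 + tolerance)
    return lo <= measured.antibodies_per_um2 <= hi
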