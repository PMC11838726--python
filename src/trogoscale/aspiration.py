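"""Interfacial tension from micropipette aspiration via the Young-Laplace law.

gamma = dP / (2 * (1/R_pipette - 1/R_cell))

Computation is carried out in SI (Pa, m, N/m); interfaces report mN/m and um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AspirationMeasurement",
    "TensionEstimate",
    "laplace_tension",
    "laplace_tension_table",
    "apply_tongue_criterion",
    "summarize_tensions",
    "QC_OK",
    "QC_TONGUE",
    "QC_GEOMETRY",
]

QC_OK = "ok"
QC_TONGUE = "tongue_criterion_not_met"
QC_GEOMETRY = "invalid_geometry"

_LENGTH_TO_M = {"um": 1e-6, "m": 1.0}


@dataclass(frozen=True)
class AspirationMeasurement:
    """One aspiration record: suction pressure plus pipette/cell geometry."""

    suction_pressure: float           # Pa
    pipette_radius: float             # length unit (default um)
    cell_radius: float                # length unit (default um)
    tongue_length: Optional[float] = None   # length unit, optional
    sample_id: str = ""


@dataclass(frozen=True)
class TensionEstimate:
    tension: float                    # mN/m (nan when geometry invalid)
    sample_id: str = ""
    qc_flag: str = QC_OK


def laplace_tension(m: AspirationMeasurement, length_unit: str = "um") -> TensionEstimate:
    """Young-Laplace tension estimate in mN/m.

    Invalid geometry (pipette radius >= cell radius, non-positive curvature
    difference) is flagged rather than raised so batch processing can
    continue; zero suction pressure legitimately gives zero tension.
    """
    scale = _LENGTH_TO_M[length_unit]
    rp = m.pipette_radius * scale
    rc = m.cell_radius * scale
    if rp <= 0 or rc <= 0 or rp >= rc:
        return TensionEstimate(tension=math.nan, sample_id=m.sample_id, qc_flag=QC_GEOMETRY)
    if m.suction_pressure < 0:
        raise ValueError("suction pressure must be >= 0")
    gamma_si = m.suction_pressure / (2.0 * (1.0 / rp - 1.0 / rc))  # N/m
    return TensionEstimate(tension=gamma_si * 1e3, sample_id=m.sample_id, qc_flag=QC_OK)


def apply_tongue_criterion(m: AspirationMeasurement, mode: str = "pipette_radius",
                           fixed: float = 1.5, tolerance: float = 0.2) -> str:
    """QC flag for the aspirated-tongue length.

    ``pipette_radius`` mode accepts tongues matching the pipette radius
    (aspiration stopped once the tongue equals it); ``fixed_length`` mode
    accepts tongues near a set length (default 1.5 um).  Tolerance is
    relative (default 20%).
    """
    if mode not in ("pipette_radius", "fixed_length"):
        raise ValueError(f"unknown tongue criterion mode: {mode!r}")
    if m.tongue_length is None:
        return QC_TONGUE
    criterion = m.pipette_radius if mode == "pipette_radius" else fixed
    if criterion <= 0:
        raise ValueError("tongue criterion must be positive")
    if abs(m.tongue_length - criterion) <= tolerance * criterion:
        return QC_OK
    return QC_TONGUE


def laplace_tension_table(df: pd.DataFrame, tongue_mode: Optional[str] = None,
                          fixed: float = 1.5, tolerance: float = 0.2) -> pd.DataFrame:
    """Vectorised tension estimation over a measurement table.

    Expects columns ``sample_id, pressure_pa, r_pipette_um, r_cell_um`` and
    optionally ``tongue_um``.  When ``tongue_mode`` is given, records failing
    the tongue criterion are flagged (tension still reported).
    """
    out_rows = []
    for row in df.itertuples(index=False):
        tongue = getattr(row, "tongue_um", None)
        if tongue is not None and isinstance(tongue, float) and math.isnan(tongue):
            tongue = None
        m = AspirationMeasurement(
            suction_pressure=row.pressure_pa,
            pipette_radius=row.r_pipette_um,
            cell_radius=row.r_cell_um,
            tongue_length=tongue,
            sample_id=str(row.sample_id),
        )
        est = laplace_tension(m)
        flag = est.qc_flag
        if flag == QC_OK and tongue_mode is not None:
            flag = apply_tongue_criterion(m, mode=tongue_mode, fixed=fixed,
                                          tolerance=tolerance)
        out_rows.append((m.sample_id, est.tension, flag))
    return pd.DataFrame(out_rows, columns=["sample_id", "tension_mN_per_m", "qc_flag"])


def summarize_tensions(estimates: Iterable[TensionEstimate],
                       group_by: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-group mean, sample SD (ddof=1) and count of QC-passing tensions.

    Groups default to each estimate's ``sample_id``.  Groups whose records are
    all flagged appear with n=0 and NaN statistics — absent data is not zero
    tension.  A single passing record reports SD as NaN.
    """
    estimates = list(estimates)
    if group_by is None:
        group_by = [e.sample_id for e in estimates]
    group_by = list(group_by)
    if len(group_by) != len(estimates):
        raise ValueError("group_by length must match estimates")
    rows = []
    seen = dict.fromkeys(group_by)  # preserves first-appearance order
    for g in seen:
        vals = np.array([e.tension for e, lab in zip(estimates, group_by)
                         if lab == g and e.qc_flag == QC_OK], dtype=float)
        n = vals.size
        mean = float(vals.mean()) if n else math.nan
        sd = float(vals.std(ddof=1)) if n > 1 else math.nan
        rows.append((g, mean, sd, n))
    return pd.DataFrame(rows, columns=["group", "mean_mN_per_m", "sd_mN_per_m", "n"])
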