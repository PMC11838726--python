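"""Synthetic data generators with known ground truth.

Every table the pipeline consumes can be generated here from a small spec
carrying its own seed, so each downstream stage is testable offline against
the generating parameters.  All randomness flows through
``numpy.random.default_rng(spec.seed)``; there is no global random state, and
a fixed seed reproduces byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .mechanics import MechanicalParams, r_min as _r_min

__all__ = [
    "CHANNELS",
    "PopulationSpec",
    "AspirationSpec",
    "DoseResponseSpec",
    "BiteSizeSpec",
    "CalibrationSpec",
    "generate_event_table",
    "generate_aspiration_table",
    "generate_dose_response",
    "generate_bite_sizes",
    "generate_calibration_table",
    "write_table_with_sidecar",
]

CHANNELS = ("green", "orange", "red")

ChannelValue = Union[float, Mapping[str, float]]


def _per_channel(value: ChannelValue, name: str) -> dict:
    if isinstance(value, Mapping):
        missing = set(CHANNELS) - set(value)
        if missing:
            raise ValueError(f"{name} missing channels: {sorted(missing)}")
        out = {c: float(value[c]) for c in CHANNELS}
    else:
        out = {c: float(value) for c in CHANNELS}
    for c, v in out.items():
        if not v > 0:
            raise ValueError(f"{name}[{c}] must be > 0")
    return out


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture of trogocytic / phagocytic / unengaged macrophages plus debris.

    Fractions ``frac_trogo`` and ``frac_phago`` apply among non-debris
    (macrophage) events; ``frac_debris`` is the fraction of CellTracker-
    negative events.  Channel intensities are lognormal with the given
    geometric mean and geometric SD; positive populations default to 20x the
    background geometric mean.
    """

    n_events: int = 10_000
    frac_trogo: float = 0.5
    frac_phago: float = 0.1
    frac_debris: float = 0.0
    background_gm: ChannelValue = 100.0
    signal_gm: ChannelValue = 2000.0
    gsd: ChannelValue = 1.5
    sample: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for name in ("frac_trogo", "frac_phago", "frac_debris"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_trogo + self.frac_phago > 1.0:
            raise ValueError("frac_trogo + frac_phago must not exceed 1")
        _per_channel(self.background_gm, "background_gm")
        _per_channel(self.signal_gm, "signal_gm")
        for c, g in _per_channel(self.gsd, "gsd").items():
            if not g > 1.0:
                raise ValueError(f"gsd[{c}] must be > 1")


# channel positivity per ground-truth class: green marks macrophages,
# red the antibody surface marker, orange the acidified volume marker
_CLASS_CHANNELS = {
    "debris": (),
    "unengaged": ("green",),
    "trogo": ("green", "red"),
    "phago": ("green", "red", "orange"),
}


def generate_event_table(spec: PopulationSpec) -> pd.DataFrame:
    """Per-event three-channel intensities with a retained ground-truth label.

    Columns: event_id, green, orange, red, sample, true_label.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.array([
        spec.frac_debris,
        (1 - spec.frac_debris) * spec.frac_trogo,
        (1 - spec.frac_debris) * spec.frac_phago,
        (1 - spec.frac_debris) * (1 - spec.frac_trogo - spec.frac_phago),
    ])
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    classes = np.array(["debris", "trogo", "phago", "unengaged"])
    labels = classes[rng.choice(4, size=spec.n_events, p=probs)]

    bg = _per_channel(spec.background_gm, "background_gm")
    sig = _per_channel(spec.signal_gm, "signal_gm")
    gsd = _per_channel(spec.gsd, "gsd")

    data = {"event_id": np.arange(spec.n_events)}
    for ch in CHANNELS:
        positive = np.isin(labels, [c for c, chans in _CLASS_CHANNELS.items()
                                    if ch in chans])
        gm = np.where(positive, sig[ch], bg[ch])
        data[ch] = gm * np.exp(np.log(gsd[ch]) * rng.standard_normal(spec.n_events))
    df = pd.DataFrame(data)
    df["sample"] = spec.sample
    df["true_label"] = labels
    return df[["event_id", "green", "orange", "red", "sample", "true_label"]]


@dataclass(frozen=True)
class AspirationSpec:
    """Aspiration records generated by running the Laplace law forward:
    dP = 2 * gamma * (1/R_pipette - 1/R_cell) + N(0, pressure_noise_sd)."""

    true_tension: float = 0.1        # mN/m
    pipette_radius: float = 2.5      # um
    cell_radius: float = 10.0        # um
    pressure_noise_sd: float = 0.0   # Pa
    n_cells: int = 10
    sample: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_tension > 0:
            raise ValueError("true_tension must be positive")
        if not 0 < self.pipette_radius < self.cell_radius:
            raise ValueError("require 0 < pipette_radius < cell_radius")
        if self.pressure_noise_sd < 0:
            raise ValueError("pressure_noise_sd must be >= 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


def generate_aspiration_table(spec: AspirationSpec) -> pd.DataFrame:
    """Columns: sample_id, pressure_pa, r_pipette_um, r_cell_um, tongue_um.

    At zero noise the tension estimator inverts these records exactly.  The
    tongue is generated at the pipette radius, satisfying the default QC
    criterion.
    """
    rng = np.random.default_rng(spec.seed)
    gamma_si = spec.true_tension * 1e-3                      # N/m
    rp_m = spec.pipette_radius * 1e-6
    rc_m = spec.cell_radius * 1e-6
    dp = 2.0 * gamma_si * (1.0 / rp_m - 1.0 / rc_m)          # Pa
    pressures = dp + spec.pressure_noise_sd * rng.standard_normal(spec.n_cells)
    return pd.DataFrame({
        "sample_id": [f"{spec.sample}_{i:04d}" for i in range(spec.n_cells)],
        "pressure_pa": pressures,
        "r_pipette_um": spec.pipette_radius,
        "r_cell_um": spec.cell_radius,
        "tongue_um": spec.pipette_radius,
    })


@dataclass(frozen=True)
class DoseResponseSpec:
    """Binomially sampled trogocytic efficiencies from a logistic in antibody
    density: p(x) = (a_true/100) * expit((x - rho_crit_true) / d_true)."""

    a_true: float = 70.0                 # plateau, %
    rho_crit_true: float = 300.0         # antibodies/um^2
    d_true: float = 50.0                 # width, antibodies/um^2
    density_grid: Sequence[float] = (25, 50, 100, 150, 200, 300, 400, 600, 800, 1200)
    n_macrophages_per_well: int = 1000
    n_replicates: int = 3
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.a_true <= 100:
            raise ValueError("a_true must be in (0, 100]")
        if not self.rho_crit_true > 0:
            raise ValueError("rho_crit_true must be positive")
        if not self.d_true > 0:
            raise ValueError("d_true must be positive")
        if len(self.density_grid) == 0:
            raise ValueError("density_grid must be non-empty")
        if self.n_macrophages_per_well <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")

    def true_efficiency(self, x) -> np.ndarray:
        """Noise-free expected efficiency (%) at density x."""
        x = np.asarray(x, dtype=float)
        return self.a_true * expit((x - self.rho_crit_true) / self.d_true)


def generate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Columns: density, efficiency, replicate, condition.

    Each well draws Binomial(n_macrophages_per_well, p(x)) trogocytic
    macrophages; efficiency is the observed percentage.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.density_grid, dtype=float)
    rows = []
    for rep in range(spec.n_replicates):
        p = spec.true_efficiency(grid) / 100.0
        counts = rng.binomial(spec.n_macrophages_per_well, p)
        eff = 100.0 * counts / spec.n_macrophages_per_well
        for x, y in zip(grid, eff):
            rows.append((x, y, rep, spec.condition))
    return pd.DataFrame(rows, columns=["density", "efficiency", "replicate", "condition"])


@dataclass(frozen=True)
class BiteSizeSpec:
    """Lognormal bite diameters whose median is the model's predicted
    minimum deformation scale at (tension, density)."""

    tension: float = 0.1        # mN/m
    density: float = 400.0      # antibodies/um^2
    geometric_sd: float = 1.5
    n_bites: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tension > 0 and self.density > 0 and self.n_bites > 0):
            raise ValueError("tension, density and n_bites must be positive")
        if not self.geometric_sd > 1:
            raise ValueError("geometric_sd must be > 1")


def generate_bite_sizes(spec: BiteSizeSpec, params: MechanicalParams) -> np.ndarray:
    """Bite diameters (um), lognormal with median r_min(tension, density)."""
    rng = np.random.default_rng(spec.seed)
    median = _r_min(spec.tension, spec.density, params)
    return median * np.exp(np.log(spec.geometric_sd) * rng.standard_normal(spec.n_bites))


@dataclass(frozen=True)
class CalibrationSpec:
    """MESF bead populations on a known linear intensity->fluorophore map."""

    slope: float = 50.0              # fluorophores per intensity unit
    intercept: float = 0.0           # fluorophores
    intensities: Sequence[float] = (100.0, 500.0, 2000.0, 8000.0, 30000.0)
    intensity_cv: float = 0.0        # relative intensity noise per bead
    n_per_level: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")
        if len(self.intensities) < 2:
            raise ValueError("need at least two bead populations")
        if self.intensity_cv < 0 or self.n_per_level <= 0:
            raise ValueError("intensity_cv >= 0 and n_per_level > 0 required")


def generate_calibration_table(spec: CalibrationSpec) -> pd.DataFrame:
    """Columns: intensity, mesf.  MESF counts sit exactly on the line; noise,
    if any, perturbs the measured intensities."""
    rng = np.random.default_rng(spec.seed)
    levels = np.repeat(np.asarray(spec.intensities, dtype=float), spec.n_per_level)
    mesf = spec.slope * levels + spec.intercept
    noisy = levels * (1.0 + spec.intensity_cv * rng.standard_normal(levels.size))
    return pd.DataFrame({"intensity": noisy, "mesf": mesf})


def write_table_with_sidecar(df: pd.DataFrame, path: Union[str, Path], spec) -> Path:
    """Write a CSV plus a ``<name>.spec.json`` sidecar recording the
    generating spec (the ground truth tests compare against)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = dataclasses.asdict(spec)
    meta["__spec__"] = type(spec).__name__
    sidecar = path.with_suffix(".spec.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=list) + "\n")
    return sidecar
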