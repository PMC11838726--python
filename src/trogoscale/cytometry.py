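"""Three-channel event gating and trogocytosis/phagocytosis classification.

Events positive for the macrophage volume dye (green), the target surface
marker (red) and the acidified-compartment dye (orange) are phagocytic;
green+/red+ but orange- events are trogocytic.  Thresholds come from control
samples: a macrophage-only control sets the orange/red background, a
target-only control sets the green background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GateThresholds",
    "EfficiencyResult",
    "derive_thresholds",
    "classify_events",
    "compute_efficiencies",
    "replicate_summary",
    "LABELS",
]

LABELS = ("debris", "unengaged", "trogo", "phago")


@dataclass(frozen=True)
class GateThresholds:
    green_thr: float
    orange_thr: float
    red_thr: float
    method: str = "control_quantile"
    quantile: float = 0.995

    def __post_init__(self) -> None:
        for name in ("green_thr", "orange_thr", "red_thr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EfficiencyResult:
    n_total_macrophage: int
    n_trogo: int
    n_phago: int
    trogo_eff: float    # %
    phago_eff: float    # %


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def derive_thresholds(macrophage_only: pd.DataFrame, target_only: pd.DataFrame,
                      quantile: float = 0.995) -> GateThresholds:
    """Per-channel positivity thresholds from control samples.

    The green threshold is a high quantile of the target-only control's green
    channel (events above it are macrophages); orange and red thresholds are
    the same quantile of the macrophage-only control (antibody/pHrodo
    background).  Default quantile 0.995 leaves <=0.5% of background events
    above each threshold.
    """
    if macrophage_only is None or len(macrophage_only) == 0:
        raise ValueError("macrophage-only control is empty")
    if target_only is None or len(target_only) == 0:
        raise ValueError("target-only control is empty")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    _require_columns(macrophage_only, ["orange", "red"], "macrophage-only control")
    _require_columns(target_only, ["green"], "target-only control")
    return GateThresholds(
        green_thr=float(np.quantile(target_only["green"], quantile)),
        orange_thr=float(np.quantile(macrophage_only["orange"], quantile)),
        red_thr=float(np.quantile(macrophage_only["red"], quantile)),
        quantile=quantile,
    )


def classify_events(t: pd.DataFrame, g: GateThresholds) -> pd.DataFrame:
    """Assign exactly one label per event.

    green- -> debris; green+/red+/orange+ -> phago; green+/red+/orange- ->
    trogo; any other green+ -> unengaged (includes the orange+/red- cell of
    the truth table, which the gating rules leave undefined).
    """
    _require_columns(t, ["green", "orange", "red"], "event table")
    green = t["green"].to_numpy() > g.green_thr
    orange = t["orange"].to_numpy() > g.orange_thr
    red = t["red"].to_numpy() > g.red_thr
    label = np.where(~green, "debris",
                     np.where(red & orange, "phago",
                              np.where(red & ~orange, "trogo", "unengaged")))
    out = t.copy()
    out["label"] = label
    return out


def compute_efficiencies(labeled: pd.DataFrame) -> EfficiencyResult:
    """Trogocytic/phagocytic efficiency as percentages of all green+ events
    (trogo + phago + unengaged macrophages)."""
    _require_columns(labeled, ["label"], "labeled table")
    counts = labeled["label"].value_counts()
    n_trogo = int(counts.get("trogo", 0))
    n_phago = int(counts.get("phago", 0))
    n_macro = n_trogo + n_phago + int(counts.get("unengaged", 0))
    if n_macro == 0:
        raise ValueError("no green-positive (macrophage) events: efficiency undefined")
    return EfficiencyResult(
        n_total_macrophage=n_macro,
        n_trogo=n_trogo,
        n_phago=n_phago,
        trogo_eff=100.0 * n_trogo / n_macro,
        phago_eff=100.0 * n_phago / n_macro,
    )


def replicate_summary(results: Iterable[EfficiencyResult]) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of efficiencies across replicates.

    A single replicate reports SD as NaN (not available), never zero.
    """
    results = list(results)
    if not results:
        raise ValueError("no replicates")
    trogo = np.array([r.trogo_eff for r in results], dtype=float)
    phago = np.array([r.phago_eff for r in results], dtype=float)
    n = len(results)

    def _row(name, vals):
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        return (name, float(vals.mean()), sd, n)

    return pd.DataFrame([_row("trogo_eff", trogo), _row("phago_eff", phago)],
                        columns=["metric", "mean_pct", "sd_pct", "n_replicates"])
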