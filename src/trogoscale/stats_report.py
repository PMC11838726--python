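"""Summary statistics (Pearson correlation, one-way ANOVA + Tukey HSD) and
report assembly."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "pearson",
    "anova_tukey",
    "build_report",
    "render_markdown",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    anova_p: float
    pairwise: List[Tuple[str, str, float, float]]  # (group_i, group_j, mean_diff, adj_p)


def pearson(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value from the t
    transform t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size:
        raise ValueError("xs and ys must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=int(x.size),
                             p_value=float(res.pvalue))


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA F-test followed by Tukey's HSD pairwise comparisons
    (studentized-range adjusted p-values; Tukey-Kramer for unbalanced
    groups)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    names = list(groups)
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        arrays.append(arr)
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(arrays[i].mean() - arrays[j].mean())
            pairwise.append((names[i], names[j], diff, float(hsd.pvalue[i, j])))
    return GroupComparison(f_statistic=float(f_stat), anova_p=float(p),
                           pairwise=pairwise)


def build_report(sections: Mapping[str, object],
                 seed: Optional[int] = None) -> dict:
    """Assemble stage outputs into one structured document.

    ``sections`` maps section names (tensions, efficiencies, densities,
    dose_response, rho_crit_vs_tension, phase_diagram, correlation, anova)
    to JSON-serialisable payloads; sections whose value is None are omitted
    entirely.  Regeneration from identical inputs is byte-identical (keys
    are sorted on serialisation, no timestamps).
    """
    present = {k: v for k, v in sections.items() if v is not None}
    if not present:
        raise ValueError("no stage outputs to report")
    doc = {"sections": present}
    if seed is not None:
        doc["seed"] = int(seed)
    # validate serialisability early, deterministically
    json.dumps(doc, sort_keys=True, default=str)
    return doc


def render_markdown(report: dict) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    lines = ["# Trogocytosis/phagocytosis analysis report", ""]
    if "seed" in report:
        lines += [f"Global seed: {report['seed']}", ""]
    for name, payload in report["sections"].items():
        lines.append(f"## {name.replace('_', ' ')}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
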