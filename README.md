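# trogoscale

Quantitative analysis of the macrophage decision between **trogocytosis**
(nibbling sub-micron membrane "bites" off a target) and **phagocytosis**
(whole-target engulfment), as a tested, reusable pipeline:

- `trogoscale.aspiration` — interfacial (cortical/membrane) tension from
  micropipette aspiration via the Young-Laplace law, with tongue-length QC.
- `trogoscale.cytometry` — control-based gating of three-channel event tables
  (cell-volume green, acidified-compartment orange, surface-antibody red) and
  classification into debris / unengaged / trogocytic / phagocytic, with
  efficiency statistics.
- `trogoscale.surface_density` — antibody surface density (antibodies/µm²)
  from fluorescence via MESF calibration beads.
- `trogoscale.dose_response` — logistic fit of efficiency vs antibody
  density, inflection-point (critical density) extraction, case-resampling
  bootstrap CIs, and the critical-density-vs-tension linear fit.
- `trogoscale.mechanics` — the scaling model `R_min = γ / (σ·ρ/ρ_ref)`:
  minimum bite scale, bending-limited scale `(κ/σ)^{1/3}`, regime
  classification, critical density/tension, and phase-diagram construction.
- `trogoscale.stats_report` — Pearson correlation, one-way ANOVA + Tukey HSD,
  report assembly.
- `trogoscale.synthetic` — generators for every input table (event tables,
  aspiration records, MESF beads, dose-response wells, bite sizes) with known
  ground truth, so the whole pipeline is testable offline.

## CLI

```sh
trogoscale simulate --seed 1 --out sim/            # synthetic inputs + ground-truth sidecars
trogoscale tension  --input sim/aspiration.csv --out tensions.csv
trogoscale classify --events sim/events.csv \
    --macrophage-control macro.csv --target-control target.csv --out labeled.csv
trogoscale density  --beads sim/beads.csv --intensity 753982 --diameter-um 10
trogoscale fit-dose --input sim/dose_response.csv --n-boot 2000 --seed 1
trogoscale phase    --out phase.csv --plot phase.png
trogoscale predict  --gamma 0.05 --rho 400
trogoscale run-all  --seed 1 --out run/            # full pipeline + report.json/report.md
```

All tabular I/O is CSV; configs are YAML or JSON; a single global seed
deterministically derives per-stage seeds, and `run-all` writes a manifest
with content hashes so identical configs reproduce identical outputs.

## Notes on calibration

The scaling law's dimensionless prefactor is fixed at 1, so absolute regime
boundaries depend on the calibration pair (`sigma_ref`, `rho_ref`) and the
interface size; defaults are σ=100 Pa at ρ=400/µm² with R=1 µm.  With these
defaults `γ_crit = σR` gives 0.05–0.15 mN/m over the 50–150 Pa stress range,
at the low edge of the ~0.1–1 mN/m switch window quoted alongside the model —
the model is order-of-magnitude, and
`mechanics.calibrate_to_switch_tension` pins the boundary to an observed
switch tension (e.g. the ~1 mN/m vesicle threshold) when an absolute
boundary is needed.
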