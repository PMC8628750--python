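# rhythmfit

Circadian analysis of replicated qPCR expression time courses: ddCt
quantification, a multi-method rhythmicity-test battery, differential
rhythmicity between conditions, and weighted fitting of a damped (or
amplifying) cosine with a linear baseline — plus a synthetic-data generator
that emulates the 0–48 h / 4 h / 6-replicate study design so every stage is
testable without raw data.

## Components

| module | what it does |
| --- | --- |
| `rhythmfit.timecourse` | `TimeCourse`: replicated values on a time grid, NaN = missing |
| `rhythmfit.synthetic` | seeded generators (damped cosine, nulls, Ct tables, presets) |
| `rhythmfit.quantify` | `2^-ddCt` relative expression, per-replicate mean normalization, replicate summaries |
| `rhythmfit.rhythm` | Lomb–Scargle permutation test, JTK-style Kendall-tau template test, RAIN-style umbrella test, harmonic regression, differential rhythmicity (Wald / label permutation) |
| `rhythmfit.cosinor` | `A e^{-λt} cos(2π(t-θ)/τ) + mt + b` weighted fit with SEs/95% CIs/R², ECHO-style bounded-period test, peak times, derived metrics, phase relationships |
| `rhythmfit.cli` | `rhythmfit` CLI: simulate / quantify / test / fit / run; deterministic seeding; CSV/TSV + JSON manifest outputs |

All permutation p-values are `(1 + #{null ≥ obs}) / (1 + N)`; grid searches
(template period × phase, umbrella peak position, bounded-period F) are
re-maximized inside every permutation, so the selection effect is part of
the null.

## CLI

```bash
# simulate the three-cell-line preset panel (expression or Ct table)
rhythmfit simulate --preset full --noise-sd 0.05 --seed 1 --out panel.csv
rhythmfit simulate --preset H16N2 --ct --seed 1 --out ct.csv

# Ct -> relative expression (ddCt, then per-replicate mean normalization)
rhythmfit quantify --in ct.csv --reference GAPDH --out expr.csv

# full analysis: battery + pairwise differential tests + parameter table
rhythmfit run --in panel.csv --out results/ --seed 1 --permutations 5000
```

`run` writes `parameter_table.csv` (one row per cell line × gene with
estimate/SE/CI95 per parameter, R², convergence flags), `rhythm_tests.tsv`,
`differential_tests.tsv`, and `manifest.json` (seed, config hash,
versions). Identical config + seed gives byte-identical outputs. A YAML
config can replace the flags (`rhythmfit run --config cfg.yaml`).

## Library example

```python
import rhythmfit as rf

panel = rf.generate_panel("H16N2", noise_sd=0.05, seed=0)
tc = rf.mean_normalize(panel[("H16N2", "BMAL1")])
fit = rf.fit_damped_cosine(tc)                     # weighted 6-parameter fit
res = rf.ls_permutation_test(tc, rf.RhythmTestConfig(seed=0))
print(fit.params.period, fit.ci95["period"], res.p_value)
```

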