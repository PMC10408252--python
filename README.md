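# regenscan

Detection of historic, partially regenerated limb loss in crabs from
cross-sectional morphometrics, plus inference of the energy-allocation
trade-offs that regeneration imposes on reproduction, energy storage and
growth.

A crab that lost a limb regrows it gradually over several molts. A limb that
is still regrowing weighs less than expected for the crab's body size, so it
can be found by fitting a per-limb allometric power law
(`mass = a * CW^b`) and flagging limbs whose mass-scale residual falls below
a negative cutoff. The summed mass of flagged limbs is a per-crab index of
the energy already sunk into regrowth; it enters additive models of organ
masses alongside current-injury counts to quantify trade-offs.

## Pipeline stages

1. **synthetic** (`regenscan.synthetic`) — generates crab populations with
   configurable limb/organ allometry, injury states (missing / limb bud /
   partially regenerated), molt-stage and seasonal variation, and linear
   trade-off effects, plus a complete truth table for recovery testing.
2. **allometry** (`regenscan.allometry`) — per-limb nonlinear least-squares
   power-law fits (log-log OLS start values), residuals, and the OLS
   calibration of limb energy content against dry mass.
3. **detection** (`regenscan.detection`) — cutoff resolution (`fixed` at
   −0.01 g by default; `gap` automates the visual break in the residual
   cloud; `quantile`), limb classification, the regenerated-mass index,
   imputation of missing-limb masses, corrected body mass, and per-limb /
   population injury summaries.
4. **models** (`regenscan.models`) — Poisson residualization of bud counts
   against missing counts (to break their collinearity), Gaussian additive
   models with penalized-spline smooths of carapace width and Julian day
   (statsmodels `GLMGam`), AIC selection of linear vs quadratic bud terms,
   presentation-only Pearson residuals, and recovery reports against
   synthetic truth.
5. **pipeline** (`regenscan.pipeline`) — CSV schema validation with a
   discard log, column-mapping for external datasets, staged orchestration,
   and a JSON run manifest with sample accounting.

## CLI

```sh
# simulate a population (writes population.csv + truth sidecars + config)
regenscan simulate --seed 1 --n-crabs 736 --out sim/

# validate, fit allometries, classify regenerating limbs
regenscan detect --input sim/population.csv --cutoff -0.01 --method fixed --out run/

# fit the four trade-off models on the detect output
regenscan model --input run/ --responses stomach,ovary,hepatopancreas,body

# figure-style residual plots
regenscan report --input run/

# or everything in one go (simulated or from a CSV)
regenscan run --seed 1 --out full/
regenscan run --input data.csv --map columns.yaml --out full/
```

External datasets are adapted with a YAML column map
(`external_name: canonical_name`); the canonical schema is one row per crab
with `crab_id, site, julian_day, carapace_width_mm`,
`limb01_status … limb10_status` (intact / missing / bud),
`limb01_mass_g … limb10_mass_g`, and dry masses `ovary_mass_g,
hepatopancreas_mass_g, stomach_mass_g, body_rest_mass_g`. Limbs are numbered
1 = right claw, clockwise to 10 = left claw.

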