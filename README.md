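# planergy

Quantitative analysis of body-size scaling and energy balance in
planarians (*Schmidtea mediterranea*).

Planarians grow when fed and literally shrink ("degrow") when starved,
reversibly, over more than three orders of magnitude in body mass. Their
whole-organism metabolic rate follows Kleiber's law, P = a·M^b with
b ≈ 3/4, across that entire range. `planergy` implements the analysis
chain by which that scaling can be traced to its physiological origin:
not a size-dependent drop in the metabolic rate *per cell*, but a
size-dependent rise in the mass (energy stores) *per cell*.

It is written for quantitative physiologists and systems biologists who
want to run the same analysis on their own measurement tables — or on
the package's synthetic emulation of them.

## What the package computes

**Scaling inference** (`planergy.powerlaw`). Every relation is a power
law y = a·x^b fitted in log-log space by iteratively reweighted least
squares with a Tukey bisquare weight (tuning constant 4.685). Fitted
laws form an algebra — `compose`, `invert`, `per_unit` — with
first-order error propagation, so derived exponents (e.g. metabolic
rate per cell versus cell number) carry standard errors from the
original fits:

    exponent(P/N ~ N) = exponent(P ~ N) − 1
    exponent(N ~ M)   = exponent(N ~ A) · exponent(A ~ M)

**Energy-balance model** (`planergy.energy`). The organismal energy
content E obeys dE/dt = J − P (influx from food minus heat loss). Three
control paradigms close the model on a per-cell basis e = E/N:

1. **dynamic reserve** — e is a free state; (1/N)dN/dt = k(e − e_set);
2. **isometric** — E = ε·N (constant reserve per cell);
3. **allometric** — E/N = e_ref·(N/N_ref)^c, so E scales as N^(1+c).

The paradigms predict different scalings of J/N, E/N and P/N with N and
are fitted to measured growth/degrowth rates (`ParadigmRateModel`; its
`fit()` returns a results object with parameters, RSS and AIC).
Simulation uses adaptive Runge–Kutta with energy conservation tracked
to integrator tolerance.

**Rates** (`planergy.rates`): exponential fits to overlapping time
windows of individual growth/degrowth traces, expressed as % change in
cell number per day, plus a permutation test for feeding-history
dependence.

**Assays and budget** (`planergy.assays`): the cell-counting
conversions (histone-H3 Western blot, image-based nuclei/bead counts),
the bead-based food-intake arithmetic (6.15 J per µl liver), Q10
temperature normalisation, the per-cell dry-mass composition budget and
the Kleiber-law cell-number extrapolation.

**Synthetic data** (`planergy.synth`): a fully deterministic generator
of every input table, calibrated to the measured study conditions
(Kleiber exponent 0.75, N~A exponent 1.19, reserve allometry c = 0.38,
P/N = 1 pW/cell, 88-fold triglyceride contrast).

## Worked example

Generate the default synthetic study and run the full pipeline:

```sh
planergy synth --seed 1 --out data/
planergy pipeline --data data/ --out report.json
```

or in Python:

```python
from planergy import GeneratorConfig, write_all_tables, run_pipeline

write_all_tables(GeneratorConfig(seed=1), "data/")
report = run_pipeline("data/")
```

Headline numbers from the seed-1 report (generating truths in
parentheses):

| quantity                     | fitted exponent | truth |
|------------------------------|-----------------|-------|
| metabolic rate ~ dry mass    | 0.753 ± 0.005   | 0.75  |
| cell number ~ plan area      | 1.201 ± 0.011   | 1.19  |
| P/N ~ N (rate per cell)      | −0.010 ± 0.014  | 0     |
| J/N ~ N (influx per cell)    | −0.028 ± 0.012  | 0     |
| E/N ~ N (energy per cell)    | 0.346 ± 0.012   | 0.38  |

The paradigm comparison ranks the allometric-reserve model first
(RSS 10.1 against ≈ 90 for the isometric and dynamic-reserve fits) with
a recovered reserve exponent c = 0.377. The physiological energy-per-
cell curve predicted from the degrowth rates at P/N ≈ 1 pW sits a
factor 2.08 below the gross (bomb-calorimetry) energy law — the
assimilation factor of about two. In the composition budget,
triglycerides change 84-fold per cell between the 4 mm and 16 mm size
classes and account for 57% of the dry-mass-per-cell increase, glycogen
for another 16%: the mass-per-cell allometry, and with it the 3/4
exponent, is mostly stored energy.

Single fits are available directly:

```sh
planergy fit --relation N~A --in data/animals.csv
# exponent b  1.1852 +/- 0.0111   (robust_bisquare, n = 80)
```

## Data formats

Input tables are plain CSV (UTF-8, `#` comments) in six schemas —
`animals`, `cohorts`, `traces`, `feeding_assay`, `bomb_calorimetry`,
`composition` — documented in `planergy.io`. Results are JSON with
stable key order. See `docs/methods.md` for the model, its parameters
and the package's numerical conventions.
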