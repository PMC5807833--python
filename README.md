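# metcycle

Kinetic modelling of the methionine metabolism cycle (MMC) in Zucker
diabetic fatty (ZDF) and control rats.

Elevated plasma homocysteine is a cardiovascular risk factor, and type-2
diabetes alters the enzymes that produce and clear it. `metcycle` implements
a seven-compartment linear kinetic model of the cycle —
methionine → S-adenosylmethionine (SAM) → S-adenosyl-L-homocysteine (SAH) →
homocysteine, with remethylation back to methionine (BHMT), transsulfuration
to cysteine (CβS), peripheral distribution compartments for both analytes,
and first-order elimination of methionine — together with the tooling a
pharmacometrician needs around it:

- **Simulation** — matrix-exponential solutions of the linear system under
  arbitrary IV bolus trains (single dose, or a "methionine-rich diet" given
  three times daily for weeks), with log-normal inter-individual variability
  on two rate constants and a combined additive + proportional residual
  error model.
- **Estimation** — nonlinear mixed-effects fitting by the Laplace
  approximation with the FOCE-style interaction convention, objective
  function values (OFV) for likelihood-ratio tests, RSEs from the numerical
  Fisher information, and conditional weighted residual (CWRES) diagnostics.
- **NCA** — model-free exposure endpoints (Cmax, Tmax, interval and total
  AUCs, the day-1 accumulation ratio AUC₈₋₁₆ₕ/AUC₀₋₈ₕ) and Welch group
  comparisons.
- **VPC** — visual predictive checks with 95% confidence bands around the
  5th/50th/95th percentiles.
- **Synthetic data** — study-shaped datasets (single 0.8 mmol/kg IV bolus,
  sampling at 0–420 min, both analytes, both groups) in a NONMEM-convention
  CSV dialect, used for estimator validation in place of the unavailable
  animal data.

## Model

Compartment amounts A₁…A₇ (mmol/kg body weight) obey dA/dt = M·A with ten
first-order rate constants (h⁻¹):

| symbol | process |
|---|---|
| K_CM, K_MC | methionine peripheral ⇄ central |
| K_MS | methionine → SAM (MAT) |
| K_SS | SAM → SAH |
| K_EL | methionine elimination |
| K_SH | SAH → homocysteine (SAH hydrolase) |
| K_HM | homocysteine → methionine (BHMT) |
| K_HC | homocysteine → cysteine (CβS) |
| K_HP, K_PH | homocysteine central ⇄ peripheral |

Plasma concentrations are central amounts divided by the apparent volume
Vc = 0.15 L/kg. Diabetic status enters as a 0/1 covariate multiplying five
rate constants, and subjects carry log-normal random effects on K_HM and
K_HP:

    K_HM,i = θ_KHM · exp(η₁ + ln f_KHM · ZDF),   η₁ ~ N(0, ω²_KHM)
    K_HP,i = θ_KHP · exp(η₂ + ln f_KHP · ZDF),   η₂ ~ N(0, ω²_KHP)

Observations follow the combined error model y = f·(1 + ε_prop) + ε_add.
The packaged presets `control` and `zdf` carry the final published
estimates (e.g. K_SH = 11.6 h⁻¹ in controls vs 13.5 h⁻¹ in ZDF rats).

## Worked example

Simulate 1000 subjects per group on day 1 of a 0.8 mmol/kg/day diet divided
into three 8-hourly doses and compute the methionine accumulation ratio:

```python
import numpy as np
import metcycle as mc

pop = mc.default_population()
reg = mc.regimen_tid(0.8, 1)            # 0.8 mmol/kg/day, one day, q8h
times = np.arange(0.0, 16.05, 0.1)

for group, label in ((0, "control"), (1, "ZDF")):
    profiles = mc.simulate_population(pop, 1000, reg, times, seed=2018,
                                      groups=(group,), noise=False)
    ars = [mc.accumulation_ratio(p.times, p.c_met) for p in profiles]
    peak = np.mean([p.c_met.max() for p in profiles])
    print(f"{label:8s} mean day-1 methionine AR = {np.mean(ars):.3f}"
          f"  (Cmax {peak:.2f} mmol/L)")

zdf = pop.group_rates(1); ctl = pop.group_rates(0)
print(f"K_SH increase in diabetic rats: {100*(zdf.K_SH/ctl.K_SH - 1):.1f}%")
```

prints

```
control  mean day-1 methionine AR = 1.124  (Cmax 1.92 mmol/L)
ZDF      mean day-1 methionine AR = 1.044  (Cmax 1.81 mmol/L)
K_SH increase in diabetic rats: 16.4%
```

An accumulation ratio above 1 means exposure in the second dosing interval
exceeds the first — methionine carried over from dose to dose. On day 1 the
control group accumulates slightly more methionine than the ZDF group
(whose remethylation of homocysteine back to methionine is much slower),
while over 60 days the slow ZDF homocysteine pool feeds back until ZDF
methionine is about twice the control level (see `docs/methods.md`).

The same steps are available from a shell:

```sh
mmc generate --n 8 --seed 1 --out study.csv
mmc fit study.csv --init control --free K_SH --out fit.json
mmc simulate --preset zdf --regimen tid:1:60 --n 100 --seed 1 --out prof.csv
mmc nca prof.csv --analyte hcy --out nca.csv
mmc vpc study.csv --model control --reps 1000 --seed 1 --out vpc.csv --plot vpc.png
```

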