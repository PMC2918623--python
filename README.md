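# aiis — closed-loop insulin infusion, in silico

`aiis` is a simulator of an automatic insulin infusion system for
hospitalized type-1 diabetic patients: a subcutaneous continuous glucose
monitor (CGM) drives a proportional–derivative insulin controller that
commands two clinical infusion pumps (regular insulin and 50% dextrose)
against a compartmental virtual patient.  It is written for control
engineers and biomedical researchers who want to stress-test artificial-
pancreas logic against worst-case glycemic challenges before any hardware
or animal work.

The package answers a concrete stability question: a subcutaneous sensor
lags blood glucose by 5–10 minutes, and delay in a feedback path is a
classic route to oscillation.  The simulator lets you challenge the closed
loop — meals, oral glucose, IV dextrose pushes, IV insulin boluses — and
measure whether glycemia stays bounded, how high it peaks, and how fast it
re-enters the 90–120 mg/dL target band.

## The model in brief

**Patient** (single extracellular glucose pool, no endogenous insulin):

    dG/dt = G_in + (NHGB − G_ren + IV)/V_g − G_out·W/V_g
    dI/dt = R/V_I − k_el·I,     dIa/dt = k_b·I − k_d·Ia

with gut absorption `G_in` fed by trapezoidal gastric emptying, net hepatic
glucose balance `NHGB(Sh·I, G)` from a monotone table with asymmetric
glucose correction, peripheral utilization `G_out` linear in active insulin
(slope c = 0.045 mg·min⁻¹·mIU⁻¹·L, scaled by Sp) and Michaelis-type in G,
and renal spill above 180 mg/dL.  IV insulin boluses follow a
two-compartment biexponential.

**Sensor**: `dS/dt = (α·G(t−T_D) − S)/τ` with α = 0.23 nA/(mg/dL),
τ = 5.77 min, T_D = 0; Gaussian noise (variance 100 nA²) on each 10-s
sample; 5-min averages clamped to 40–400 mg/dL → 288 readings/day.

**Controller** (every 5 min, readings G0, G5, G10):

    A   = 0.4·G0 − 0.4·G10
    DF  = K2·A/√(1 + K1·A²)          K1 = 1 (mg/dL)⁻², K2 = 10
    IR' = (M/2)(1 + tanh(S·(G0 + DF − B)))
    GR' = K_G·max(0, 60 − G0)

with an emergency switch: below 60 mg/dL the insulin line falls to its
keep-vein-open minimum (1 mL/h ≈ 1 IU/h) and the dextrose line activates.

**Pumps**: rates quantized to 0.1 mL/h in [1, 500] mL/h; insulin never
below KVO.

See `docs/methods.md` for every equation, unit, default and the
calibration procedure behind the defaults.

## Worked example

Severe challenge — 10 g of glucose (20 mL of 50% dextrose) pushed IV over
30 s at hour 10 of a 24-h run, 70-kg patient, average hepatic sensitivity:

```bash
$ aiis run --scenario severe --seed 1 --out out/severe
peak=182.3 mg/dL  over140=14 min  nadir=73.7 mg/dL  Ts=97.83333333337123
timeseries: out/severe/timeseries.csv
metrics: out/severe/metrics.csv
config: out/severe/config.json
```

Reading: the bolus drives glycemia to a **182 mg/dL** peak; the controller
answers with a burst of insulin that ends the hyperglycemic overshoot
(>140 mg/dL) after **14 minutes**; the insulin tail then pushes glucose
down to a **74 mg/dL** trough — above the 60 mg/dL hypoglycemia line, so
the dextrose pump stays quiet — and the loop stabilizes back inside the
90–120 mg/dL band **98 minutes** after the challenge.  `timeseries.csv`
holds the 10-s trace (true and sensed glucose, delivered insulin and
dextrose rates, plasma insulin); `aiis plot out/severe` renders the
three-panel figure.

Other entry points:

```bash
aiis run --scenario mild --weight 70 --sh 0.5 --seed 3 --out out/mild
aiis sweep --table 1 --replicates 11 --seed 0 --out out/sweep   # full grid
aiis validate my_config.yaml
```

or from Python:

```python
from aiis import build_scenario, run_closed_loop
res = run_closed_loop(scenario=build_scenario("moderate"), seed=7)
print(res.metrics.overshoot_peak, res.metrics.settling_time)
```

Everything is configurable through a YAML/JSON file (`patient`, `sensor`,
`controller`, `insulin_pump`, `glucose_pump`, `engine`, `scenario` blocks);
unknown keys are rejected, and every run snapshots its fully-defaulted
configuration next to its outputs.

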