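# Methods

`aiis` simulates a complete closed-loop intravenous insulin-infusion system
for an ICU-style type-1 diabetic patient: a compartmental glucose–insulin
model of the patient, a subcutaneous continuous glucose monitor (CGM) with
first-order lag and amperometric noise, a proportional–derivative (PD)
insulin controller built on a hyperbolic tangent with an emergency dextrose
rescue, and two volumetric infusion pumps with quantized flow rates.  This
note records the model equations, the unit conventions, the calibration of
every constant that is not fixed by the published operating points, and the
known limitations of the approach.

## 1. Virtual patient

The patient has **zero endogenous insulin secretion**.  State variables:
glycemia `G` (mg/dL) in a single extracellular pool, plasma insulin `I`
(mIU/L ≡ µIU/mL), an "active insulin" pool `Ia` (mIU/L) that lags plasma
insulin and drives glucose utilization, and gut glucose `Ggut` (mg).

**Glucose balance** (internally mg/dL/min; the flux API reports per hour):

```
dG/dt = G_in + (NHGB − G_ren + 60·F_iv)/V_g − G_out·W/V_g
```

with `V_g = 1.7 dL/kg × W` the glucose distribution volume, `F_iv` any
intravenous glucose (mg/min: challenge boluses and the rescue pump),
`G_in = 60·F_abs/V_g` the systemic appearance from the gut (mg/dL/h),
`G_out` total utilization (mg/kg/h) and `G_ren` renal excretion (mg/h).

**Meals.**  Gastric emptying follows a symmetric trapezoid (ramp–plateau–
ramp) whose integral equals the carbohydrate mass; small meals degenerate to
a triangle with the same ramp slope.  A complex-carbohydrate meal empties at
`complex_cho_factor` (default 0.85) of the oral-glucose maximum
(`gastric_vmax`, default 800 mg/min; ramps 40 min).  Gut glucose is absorbed
with a saturating law `F_abs = Vmax·Ggut/(K + Ggut)` (defaults 2000 mg/min,
K = 10 g).  These are *effective* rates: the single gut pool absorbs the
unmodeled intestinal transit, so the emptying maximum is faster than a
literal gastric rate would be.  Mass is conserved exactly: everything
emptied is eventually absorbed.

**Peripheral utilization.**

```
G_out = u0 + 60·c·(Sp/0.5)·Ia·M(G),   M(G) = G(Km+100)/(100(Km+G))
```

`u0` is the insulin-independent (CNS + red cell) uptake, 78.2 mg/kg/h.  The
insulin slope `c = 0.045 mg·min⁻¹·mIU⁻¹·L` applies per kilogram at the
reference glycemia (M(100) = 1) for the average peripheral sensitivity
Sp = 0.5, and the dependence is linear in active insulin and Michaelis-type
in glucose (Km = 250 mg/dL, i.e. close to linear over the clinical range).

**Net hepatic glucose balance (NHGB).**  Hepatic production minus uptake is
a piecewise-linear, monotone non-increasing table in *effective insulin*
`Sh·I`, evaluated at the reference glycemia and corrected linearly in
glucose, clipped to the table endpoints, and scaled by `W/70` (liver output
scales with body size):

| Sh·I (mIU/L) | 0 | 4 | 16 | 28 | 40 | 60 | 100 | 400 |
|---|---|---|---|---|---|---|---|---|
| NHGB (mg/h) | 16000 | 9000 | 9000 | 0 | −1500 | −3000 | −4500 | −12000 |

The glucose correction is asymmetric: −325 mg/h per mg/dL above 100 mg/dL
(hepatic autoregulation plus glycogen synthesis), +120 mg/h per mg/dL below
it, plus an additional +400 mg/h per mg/dL below 75 mg/dL representing the
steep glucagon/epinephrine counter-regulatory response to frank
hypoglycemia.  The flat segment between Sh·I = 4 and 16 makes the basal
operating point insensitive to Sh (all patients idle near 100 mg/dL on the
same keep-vein-open infusion), while the steep drop beyond 16 differentiates
hepatic sensitivities during meals — the less sensitive patient keeps
producing glucose while insulin rises, giving higher excursion peaks.

**Renal excretion** is zero up to the 180 mg/dL threshold and linear above
it (72 mg/h per mg/dL, roughly a 120 mL/min glomerular filtration).

**Insulin kinetics.**

```
dI/dt  = R/V_I − k_el·I          (R in mIU/min)
dIa/dt = k_b·I_total − k_d·Ia
```

`V_I = 9.94 L`, `k_el = 0.09 min⁻¹`, so a constant infusion R settles at
`I = R/(k_el·V_I)`; the keep-vein-open 1 IU/h gives 18.6 µIU/mL, matching
the reported ≈20 µIU/mL basal insulinemia.  The active pool uses
`k_b = k_d = 0.32 min⁻¹` (≈3-min lag), fast enough that the insulin burst
after an IV glucose bolus clears the hyperglycemia in ≈15 min.

**IV insulin bolus.**  A bolus dose is tracked analytically with the
standard two-compartment biexponential for the central concentration,
`c(t) = (D/V1)(A₁e^(−λ₁t) + A₂e^(−λ₂t))`, additive to the infusion-driven
plasma insulin.  Defaults `k12 = 0.15`, `k21 = 0.07`, `k_el = 0.25 min⁻¹`,
`V1 = 3.0 L`: a 10-IU push peaks at 3333 µIU/mL, matching the reported
≈3300 µIU/mL.

**Integration.**  Fixed-step classical RK4 with `dt = 1/12 min` (5 s), two
steps per 10-s sensor sample so the patient clock nests exactly inside the
sensor clock.  Halving `dt` moves a 24-h trajectory by < 0.5 mg/dL, and the
integrator agrees with an explicit-Euler reference at `dt = 0.001 min`
within 0.1 mg/dL over a 6-h meal trajectory (both regression-tested).
Negative states are clipped to zero with a logged warning (physiological
floors); NaN/Inf aborts with the offending variable named.

## 2. CGM sensor

The sensor current obeys `dS/dt = (α·G(t−T_D) − S)/τ` with gain
`α = 0.23 nA per mg/dL`, time constant `τ = 5.77 min` and transport delay
`T_D = 0` (implemented as a ring buffer so nonzero delays are testable).
The lag is advanced with its exact zero-order-hold solution each 10-s
sample, so a glucose step reaches `1 − 1/e` = 63.2% of its equilibrium
change at exactly `t = τ`.  White Gaussian noise (mean 0, variance
100 nA² — the variance is interpreted on the current signal, and is
configurable) is added to every 10-s raw sample; 30 samples are averaged
every 5 min, divided by α and clamped to the 40–400 mg/dL reporting range:
288 estimates per day.  Averaging reduces the reading noise variance 30-
fold, leaving σ ≈ 1.8 nA ≈ 7.9 mg/dL per reading — this reading noise is
what limits how steep the controller law can usefully be (§5).

## 3. Controller

Executed once per 5-min reading, using the last three readings G0, G5, G10:

```
A   = a0·G0 + a5·G5 + a10·G10          (a0, a5, a10) = (0.4, 0, −0.4)
DF  = K2·A / sqrt(1 + K1·A²)            K1 = 1 (mg/dL)⁻², K2 = 10
IR' = (M/2)·(1 + tanh(S·(G0 + DF − B)))
GR' = K_G·max(0, G_crit − G0)
```

If `G0 < G_crit = 60 mg/dL` the insulin line drops to its minimum
(`IR_min` = keep-vein-open, 1 IU/h — never zero, to avoid catheter
occlusion and ketoacidotic lipolysis) and the dextrose line runs at GR';
otherwise insulin runs at `max(IR', IR_min)` and the dextrose line is off.
Recovery above `G_crit` restores normal operation at the next reading.

*Trend coefficients.*  The zero-sum constraint `a0 + a5 + a10 = 0` is
enforced at validation (constant glycemia ⇒ no derivative action).  The
default filter is the symmetric first difference over the 10-min window
scaled to a 4-minute aggregate (a 1 mg/dL/min ramp gives A = 4 mg/dL).  A
backward-difference stencil (1.2, −1.6, 0.4) estimates the same trend but
amplifies reading-noise variance 13-fold (4.16 vs 0.32), which saturates DF
permanently at ±K2/√K1 = ±10 mg/dL under the default sensor noise; the
symmetric filter is used instead.  `aiis.calibrate.fit_trend_coefficients`
re-derives the coefficients by constrained least squares against any
user-supplied reference glycemia profile.

*Differential factor.*  DF is odd, has small-signal gain K2 and saturates
at ±K2/√K1 — a bounded derivative action consistent with the printed units
of K1 and K2.

*Tuning.*  M = 200 mIU/min (12 IU/h) is the severe-challenge ceiling.
S = 0.05 dL/mg and B = 150 mg/dL were calibrated (§5) so that the noisy
closed loop idles at ≈100 mg/dL commanding ≈1.0 IU/h, and a 150 mg/dL
excursion commands mid-range insulin.  `K_G = 10 (mL/h)/(mg/dL)` recovers a
deep insulin-bolus hypoglycemia within minutes without rebound
hyperglycemia above 140 mg/dL.

## 4. Pumps and units

Both lines model a clinical volumetric pump: rates quantized to 0.1 mL/h
(ties round half-up, for bit-reproducibility), clamped to [1.0, 500] mL/h
while active; the insulin line never drops below the 1.0 mL/h keep-vein-open
rate, the dextrose line delivers zero between emergencies.  The controller
works in mIU/min; the pump boundary owns the conversion via the solution
concentrations — insulin 1 IU/mL (so KVO = 1 IU/h basal) and 50% dextrose
(500 mg/mL).  Rate changes take effect instantly at the 5-min controller
boundary.

## 5. Calibration of free constants

The published description fixes the architecture, the sensor constants
(α, τ, T_D, noise variance, saturations, cadence), the controller constants
K1, K2, G_crit, the reference/band/hypoglycemia levels, the pump limits and
the challenge definitions — but *not* the patient-model numbers, the trend
coefficients, or M, S, B, K_G.  Those were calibrated, by direct simulation
of the full closed loop (parameter scans over the gastric, hepatic,
insulin-action and controller constants), against the published operating
anchors of the same system:

* basal: ≈1.0 IU/h commanded and ≈20 µIU/mL plasma insulin pre-challenge;
* mild challenge (50 g complex CHO): peak ≈150 mg/dL, settling ≈90 min;
* moderate (50 g oral glucose): peak ≈170 mg/dL, settling ≈60 min;
* severe (10 g IV over 30 s): peak ≈180 mg/dL, ≈15 min above 140 mg/dL,
  settling ≈120 min, no undershoot;
* negative (10 IU IV insulin): nadir ≈12 mg/dL at average sensitivity,
  recovered within minutes by the rescue pump;
* across the weight × Sh grid: no undershoot after any positive challenge,
  overshoot peaks non-increasing in Sh, insulin-bolus nadir deeper at
  higher sensitivity.

The frozen defaults reproduce all anchors within the tolerances used by the
test suite (peaks ±15%, timings ±33%, basal quantities ±25%) except the
moderate-challenge settling time, which stabilizes at ≈85 min instead of
≤80.  This is a structural consequence of the sensor noise: with
σ ≈ 8 mg/dL per reading, the tanh slope cannot be made steep enough near
the reference for the loop to dispose a 50-g glucose load inside an hour —
pushing the meal in faster raises the peak and triggers a post-meal
hypoglycemic dip whose recovery lengthens the settling time instead
(verified by scans on both sides of the chosen emptying rate).  The value
is reported as measured.

## 6. Scenarios, metrics and sweeps

Each experiment is a 24-h run with one challenge at minute 600 (10:00 h);
the preceding 10 h of closed loop serve as warm-up so the system is at its
noisy steady state when challenged.  Metrics are computed on **true**
glycemia from the challenge onward: overshoot peak and minutes above
140 mg/dL, undershoot nadir and minutes below 60 mg/dL, and two settling
times — the *stabilization* time (entry into 90–120 mg/dL with residence
for the rest of the horizon; the primary value) and the first band entry
(secondary).  A run that never stabilizes reports an undefined settling
time rather than a fabricated one.  The sweep runs every
(challenge, weight ∈ {60, 70, 80} kg, Sh ∈ {0.3, 0.5, 0.7}) cell for 11
seeded replicates (odd, for unambiguous medians) and reports per-cell
medians; the per-run rows are kept alongside.

Sensor noise is the only stochastic element; it draws from one named
generator seeded per run, and replicate seeds derive from a master seed via
a splitting sequence, so every run, sweep and output file is
bit-reproducible from (config, seed).

## 7. What the simulator does and does not show

The virtual patient is a deliberately small compartmental model with
effective, calibrated constants.  It reproduces the closed-loop *operating
points* of the real system description; it does not model circadian
insulin-sensitivity variation, counter-regulatory hormone dynamics beyond a
static NHGB correction, subcutaneous insulin absorption (insulin is
intravenous by design), sensor calibration drift or dropouts, meal
announcement, or multi-day wear.  Passing tests therefore demonstrate the
stability and safety logic of the *control system* under the modeled
conditions — not clinical performance on real patients.  The severe
challenge's 45-min spell of minimal infusion after the insulin burst is an
emergent property of the PD law (falling glycemia drives DF to its negative
bound and the tanh to its floor), not a programmed timer.

## 8. Numerical details worth knowing

* RK4 with inputs held constant over each step; challenge fluxes are
  time-dependent inside the step (the 30-s IV bolus spans six patient
  steps).
* The 2-s insulin push is treated as an instantaneous dose at its midpoint
  (its duration is far below the integration step).
* NHGB interpolation is linear with bisection; the glucose corrections are
  applied before clipping to the table endpoints.
* Settling times are resolved on the 10-s recording grid; durations are
  accumulated sample time.
* Pump-rate ties (e.g. 2.35 mL/h) round half-up by `floor(x/step + 0.5)`.
* The loop starts at the reference glycemia with insulin at the basal
  steady state; the 10-h warm-up erases any residual transient.
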