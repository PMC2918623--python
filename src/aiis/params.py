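"""Parameter containers and validation for every block of the closed loop.

All tunable constants of the simulator live here, in plain dataclasses whose
field names are also the keys accepted in YAML/JSON configuration files.
Units are stated per field; the module-level ``*_DEFAULTS`` instances are the
documented reference parameterization of the system (a 70-kg type-1 diabetic
with average insulin sensitivities, a Guardian-class subcutaneous sensor and
two IMED Gemini PC-1 pumps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence


class ConfigError(ValueError):
    """A parameter violates its documented constraint."""


def _require(cond: bool, key: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"parameter '{key}' violates constraint: {constraint}")


@dataclass
class PatientParams:
    """Physiology of the simulated type-1 diabetic (no endogenous insulin).

    The glucose side is a single extracellular compartment fed by gut
    absorption and net hepatic glucose balance (NHGB) and drained by
    insulin-independent utilization (CNS + red cells), insulin-dependent
    peripheral utilization and renal excretion above the renal threshold.
    The insulin side is a plasma pool with first-order elimination plus a
    lagged "active insulin" pool that drives glucose utilization.
    """

    body_weight: float = 70.0          # kg
    Sh: float = 0.5                    # hepatic insulin sensitivity, 0..1
    Sp: float = 0.5                    # peripheral insulin sensitivity, 0..1
    c: float = 0.045                   # slope of peripheral utilization vs insulin, mg/min per mIU/L (per kg)
    renal_threshold: float = 180.0     # mg/dL above which the kidney spills glucose
    renal_clearance: float = 72.0      # mg/h excreted per mg/dL above threshold
    glucose_dist_volume: float = 1.7   # dL/kg, glucose distribution space
    insulin_dist_volume: float = 9.94  # L, plasma insulin distribution volume
    insulin_elim_rate: float = 0.09    # 1/min, first-order plasma insulin elimination
    active_insulin_rates: tuple[float, float] = (0.32, 0.32)  # 1/min (build-up, deactivation)
    insulin_independent_util: float = 78.2  # mg/kg/h, CNS + red-cell uptake

    # -- peripheral utilization shape --------------------------------------
    sp_ref: float = 0.5                # Sp at which `c` applies unscaled
    glucose_michaelis_km: float = 250.0  # mg/dL, Michaelis constant of uptake vs G
    glucose_ref: float = 100.0         # mg/dL, normalization point of the uptake curve

    # -- net hepatic glucose balance ---------------------------------------
    # Piecewise-linear table NHGB(effective insulin Sh*I) in mg/h, evaluated
    # at glucose_ref; monotone non-increasing.  A linear glucose correction
    # (mg/h per mg/dL below glucose_ref) is added and the result clipped to
    # the table endpoints.
    nhgb_table: tuple[tuple[float, float], ...] = (
        (0.0, 16000.0),
        (4.0, 9000.0),
        (16.0, 9000.0),
        (28.0, 0.0),
        (40.0, -1500.0),
        (60.0, -3000.0),
        (100.0, -4500.0),
        (400.0, -12000.0),
    )
    nhgb_glucose_slope: float = 325.0  # mg/h per mg/dL of (glucose_ref - G), G above glucose_ref
    nhgb_hypo_slope: float = 120.0     # mg/h per mg/dL below glucose_ref (counter-regulation)
    nhgb_weight_ref: float = 70.0      # kg; NHGB scales linearly with body_weight/this
    nhgb_rescue_threshold: float = 75.0  # mg/dL; stronger counter-regulation below this
    nhgb_rescue_slope: float = 400.0   # extra mg/h per mg/dL below the rescue threshold

    # -- gastric emptying & gut absorption ---------------------------------
    gastric_vmax: float = 800.0        # mg/min, maximal gastric emptying rate (oral glucose)
    gastric_ramp: float = 40.0         # min, rise/fall time of the trapezoidal profile
    complex_cho_factor: float = 0.85   # emptying slowdown for complex-CHO meals vs oral glucose
    gut_absorption_vmax: float = 2000.0  # mg/min, saturating gut->blood absorption rate
    gut_absorption_half: float = 10000.0  # mg of gut glucose at half-maximal absorption

    def validate(self) -> "PatientParams":
        _require(self.body_weight > 0, "body_weight", "> 0")
        _require(0.0 <= self.Sh <= 1.0, "Sh", "0 <= Sh <= 1")
        _require(0.0 <= self.Sp <= 1.0, "Sp", "0 <= Sp <= 1")
        _require(self.c > 0, "c", "> 0")
        _require(self.renal_threshold > 0, "renal_threshold", "> 0")
        _require(self.renal_clearance >= 0, "renal_clearance", ">= 0")
        _require(self.glucose_dist_volume > 0, "glucose_dist_volume", "> 0")
        _require(self.insulin_dist_volume > 0, "insulin_dist_volume", "> 0")
        _require(self.insulin_elim_rate > 0, "insulin_elim_rate", "> 0")
        _require(len(self.active_insulin_rates) == 2, "active_insulin_rates",
                 "(build-up, deactivation) pair")
        _require(all(k > 0 for k in self.active_insulin_rates),
                 "active_insulin_rates", "all > 0")
        _require(self.insulin_independent_util >= 0, "insulin_independent_util", ">= 0")
        _require(0 < self.sp_ref <= 1.0, "sp_ref", "0 < sp_ref <= 1")
        _require(self.glucose_michaelis_km > 0, "glucose_michaelis_km", "> 0")
        _require(self.glucose_ref > 0, "glucose_ref", "> 0")
        _require(self.nhgb_glucose_slope >= 0, "nhgb_glucose_slope", ">= 0")
        _require(self.nhgb_hypo_slope >= 0, "nhgb_hypo_slope", ">= 0")
        _require(self.nhgb_weight_ref > 0, "nhgb_weight_ref", "> 0")
        _require(0 < self.nhgb_rescue_threshold <= self.glucose_ref,
                 "nhgb_rescue_threshold", "in (0, glucose_ref]")
        _require(self.nhgb_rescue_slope >= 0, "nhgb_rescue_slope", ">= 0")
        tab = tuple(tuple(map(float, row)) for row in self.nhgb_table)
        _require(len(tab) >= 2, "nhgb_table", "at least two points")
        xs = [x for x, _ in tab]
        ys = [y for _, y in tab]
        _require(all(b > a for a, b in zip(xs, xs[1:])), "nhgb_table",
                 "insulin abscissae strictly increasing")
        _require(all(b <= a for a, b in zip(ys, ys[1:])), "nhgb_table",
                 "NHGB monotone non-increasing in effective insulin")
        _require(self.gastric_vmax > 0, "gastric_vmax", "> 0")
        _require(self.gastric_ramp > 0, "gastric_ramp", "> 0")
        _require(0 < self.complex_cho_factor <= 1.0, "complex_cho_factor", "in (0, 1]")
        _require(self.gut_absorption_vmax > 0, "gut_absorption_vmax", "> 0")
        _require(self.gut_absorption_half > 0, "gut_absorption_half", "> 0")
        return self

    @property
    def glucose_volume_dl(self) -> float:
        """Total glucose distribution volume, dL."""
        return self.glucose_dist_volume * self.body_weight


@dataclass
class BolusInsulinModel:
    """Two-compartment kinetics of an intravenous regular-insulin bolus.

    The central-compartment concentration after a dose D is the standard
    biexponential  (D/V1)*(A1*exp(-l1*t) + A2*exp(-l2*t)); its contribution
    is added on top of the infusion-driven plasma insulin.
    """

    k12: float = 0.15   # 1/min, central -> peripheral transfer
    k21: float = 0.07   # 1/min, peripheral -> central transfer
    k_el: float = 0.25  # 1/min, elimination from the central compartment
    V1: float = 3.0     # L, central volume (10 IU then peaks at ~3333 mIU/L)

    def validate(self) -> "BolusInsulinModel":
        for key in ("k12", "k21", "k_el", "V1"):
            _require(getattr(self, key) > 0, key, "> 0")
        return self


@dataclass
class SensorParams:
    """Subcutaneous amperometric CGM: first-order lag, gain, noise, averaging."""

    alpha: float = 0.23          # nA per mg/dL, sensitivity
    tau: float = 5.77            # min, time constant of the interstitial lag
    T_D: float = 0.0             # min, pure transport delay
    noise_variance: float = 100.0  # nA^2, white Gaussian noise on each raw sample
    sample_period: float = 10.0  # s, raw sampling interval
    averaging_window: float = 5.0  # min, reporting (averaging) interval
    sat_low: float = 40.0        # mg/dL, lower reporting limit
    sat_high: float = 400.0      # mg/dL, upper reporting limit

    def validate(self) -> "SensorParams":
        _require(self.alpha > 0, "alpha", "> 0")
        _require(self.tau > 0, "tau", "> 0")
        _require(self.T_D >= 0, "T_D", ">= 0")
        _require(self.noise_variance >= 0, "noise_variance", ">= 0")
        _require(self.sample_period > 0, "sample_period", "> 0")
        _require(self.averaging_window > 0, "averaging_window", "> 0")
        n = self.averaging_window * 60.0 / self.sample_period
        _require(abs(n - round(n)) < 1e-9 and round(n) >= 1, "averaging_window",
                 "must hold an integer number of raw samples")
        _require(self.sat_low < self.sat_high, "sat_low", "< sat_high")
        return self

    @property
    def samples_per_reading(self) -> int:
        return round(self.averaging_window * 60.0 / self.sample_period)


@dataclass
class ControllerParams:
    """Tanh PD insulin law, proportional glucose rescue and emergency logic.

    The insulin law is IR' = (M/2)*(1 + tanh(S_slope*(G0 + DF - B))) with the
    differential factor DF = K2*A/sqrt(1 + K1*A^2), A = a0*G0 + a5*G5 + a10*G10.
    Defaults for M, S_slope and B are calibrated so the loop commands ~1 IU/h
    at the 100 mg/dL reference and ~7 IU/h at 150 mg/dL, with a 12 IU/h
    ceiling (see docs/methods.md for the calibration procedure).
    """

    M: float = 200.0        # mIU/min, maximal insulin infusion (12 IU/h)
    S_slope: float = 0.05   # dL/mg, slope of the tanh curve
    B: float = 150.0        # mg/dL, glycemia of half-maximal infusion
    K1: float = 1.0         # (mg/dL)^-2, differential-factor parameter
    K2: float = 10.0        # dimensionless differential-factor gain
    a0: float = 0.4         # weight of the latest reading in A
    a5: float = 0.0         # weight of the 5-min-old reading
    a10: float = -0.4       # weight of the 10-min-old reading
    IR_min: float = 50.0 / 3.0  # mIU/min, minimum insulin infusion (KVO, 1 IU/h)
    G_crit: float = 60.0    # mg/dL, hypoglycemia threshold triggering rescue
    K_G: float = 10.0       # (mL/h)/(mg/dL), glucose-rescue proportional gain
    G_ref: float = 100.0    # mg/dL, reference glycemia
    band_low: float = 90.0  # mg/dL, acceptable-range floor
    band_high: float = 120.0  # mg/dL, acceptable-range ceiling

    def validate(self) -> "ControllerParams":
        _require(self.IR_min >= 0, "IR_min", ">= 0")
        _require(self.M > self.IR_min, "M", "> IR_min")
        _require(self.S_slope > 0, "S_slope", "> 0")
        _require(self.B > 0, "B", "> 0")
        _require(self.K1 >= 0, "K1", ">= 0")
        _require(self.K2 >= 0, "K2", ">= 0")
        _require(abs(self.a0 + self.a5 + self.a10) < 1e-9, "a0+a5+a10",
                 "must sum to zero so constant glycemia gives A = 0")
        _require(self.K_G > 0, "K_G", "> 0")
        _require(self.band_low < self.band_high, "band_low", "< band_high")
        _require(self.G_crit < self.band_low, "G_crit", "< band_low")
        return self


@dataclass
class PumpSpec:
    """IMED Gemini PC-1 style volumetric pump: quantized rate, KVO floor."""

    rate_min: float = 1.0       # mL/h, minimal deliverable rate when active
    rate_max: float = 500.0     # mL/h
    rate_step: float = 0.1      # mL/h, rate quantum
    kvo_rate: float = 1.0       # mL/h, keep-vein-open rate
    concentration: float = 1.0  # drug per mL (insulin IU/mL or glucose mg/mL)

    def validate(self) -> "PumpSpec":
        _require(self.rate_min > 0, "rate_min", "> 0")
        _require(self.rate_min <= self.kvo_rate <= self.rate_max, "kvo_rate",
                 "rate_min <= kvo_rate <= rate_max")
        _require(self.rate_step > 0, "rate_step", "> 0")
        _require(self.concentration > 0, "concentration", "> 0")
        return self


# Glucose rescue line: 50% dextrose-in-water, 500 mg glucose per mL.
GLUCOSE_PUMP_DEFAULTS = PumpSpec(concentration=500.0)
INSULIN_PUMP_DEFAULTS = PumpSpec(concentration=1.0)


@dataclass
class EngineParams:
    """Orchestration constants of the 24-h closed-loop run."""

    dt: float = 1.0 / 12.0       # min, patient integration step (nests in 10-s sampling)
    duration: float = 1440.0     # min, simulation span
    challenge_time: float = 600.0  # min, clock time of the single perturbation (10:00 h)
    replicates: int = 11         # replicate count for sweep medians

    def validate(self) -> "EngineParams":
        _require(self.dt > 0, "dt", "> 0")
        _require(self.duration > 0, "duration", "> 0")
        _require(0 <= self.challenge_time <= self.duration, "challenge_time",
                 "within the simulated span")
        _require(self.replicates >= 1, "replicates", ">= 1")
        return self


def from_mapping(cls, data: dict, where: str):
    """Build a parameter dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{where}' block: {sorted(unknown)}; "
            f"allowed: {sorted(known)}")
    coerced = dict(data)
    if "active_insulin_rates" in coerced:
        coerced["active_insulin_rates"] = tuple(coerced["active_insulin_rates"])
    if "nhgb_table" in coerced:
        coerced["nhgb_table"] = tuple(tuple(row) for row in coerced["nhgb_table"])
    return cls(**coerced).validate()


__all__ = [
    "ConfigError",
    "PatientParams",
    "BolusInsulinModel",
    "SensorParams",
    "ControllerParams",
    "PumpSpec",
    "EngineParams",
    "GLUCOSE_PUMP_DEFAULTS",
    "INSULIN_PUMP_DEFAULTS",
    "from_mapping",
    "replace",
]
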