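"""Virtual type-1 diabetic patient: a compartmental glucose/insulin ODE model.

The model follows the classic single-extracellular-pool structure: glycemia G
changes with gut absorption (G_in), net hepatic glucose balance (NHGB),
peripheral + insulin-dependent utilization (G_out) and renal excretion
(G_ren); plasma insulin I is a first-order pool fed by intravenous infusion;
a lagged active-insulin pool Ia drives glucose utilization.  The patient has
zero endogenous insulin secretion.  Subcutaneous insulin absorption is
deliberately absent: insulin enters intravenously only.

Unit conventions (documented, every quantity converted explicitly):
  G      mg/dL          Ia        mIU/L
  I      mIU/L (= uIU/mL numerically)
  Ggut   mg             NHGB      mg/h (internal convention)
  G_in   mg/dL/h        G_out     mg/kg/h
  G_ren  mg/h           infusion  mIU/min (insulin), mg/min (glucose)
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass

from .params import BolusInsulinModel, PatientParams

log = logging.getLogger(__name__)

MEAL_KINDS = ("meal_complex_CHO", "oral_glucose")
EVENT_KINDS = MEAL_KINDS + ("iv_glucose_bolus", "iv_insulin_bolus")


class InvalidEventError(ValueError):
    """Challenge event with non-physical fields."""


class IntegrationError(RuntimeError):
    """The ODE state became non-finite."""


@dataclass
class ChallengeEvent:
    """A single timed perturbation.

    amount is grams of carbohydrate/glucose for oral and IV-glucose events
    and IU of regular insulin for IV-insulin events.  duration is in minutes
    (0.5 min for the IV dextrose push, 2 s = 1/30 min for the insulin bolus).
    """

    kind: str
    t_start: float
    amount: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InvalidEventError(f"unknown event kind '{self.kind}'")
        if not self.amount > 0:
            raise InvalidEventError("event amount must be > 0")
        if self.duration < 0:
            raise InvalidEventError("event duration must be >= 0")


@dataclass
class PatientState:
    """Instantaneous physiological state."""

    G: float = 100.0        # mg/dL
    I: float = 0.0          # mIU/L plasma insulin (infusion-driven part)
    Ia: float = 0.0         # mIU/L active insulin pool
    Ggut: float = 0.0       # mg glucose in gut
    Gstomach: float = 0.0   # mg carbohydrate left in stomach
    t: float = 0.0          # min


def _gastric_profile(event: ChallengeEvent, p: PatientParams):
    """Trapezoidal (or small-meal triangular) emptying profile parameters.

    Returns (vpeak mg/min, ramp min, plateau min); the profile ramps up over
    `ramp`, holds `vpeak` for `plateau`, ramps down over `ramp`, and its
    time-integral equals the meal's carbohydrate mass.
    """
    vmax = p.gastric_vmax
    if event.kind == "meal_complex_CHO":
        vmax *= p.complex_cho_factor
    mass = event.amount * 1000.0  # g -> mg
    if mass >= vmax * p.gastric_ramp:
        return vmax, p.gastric_ramp, mass / vmax - p.gastric_ramp
    # small meal: symmetric triangle with the same ramp slope
    half = math.sqrt(mass * p.gastric_ramp / vmax)
    return vmax * half / p.gastric_ramp, half, 0.0


def gastric_emptying_flux(state: PatientState, event: ChallengeEvent,
                          p: PatientParams) -> float:
    """Stomach -> gut glucose flux (mg/min) at state.t for one meal event."""
    if event.kind not in MEAL_KINDS:
        return 0.0
    tau = state.t - event.t_start
    if tau <= 0.0:
        return 0.0
    vpeak, ramp, plateau = _gastric_profile(event, p)
    if tau < ramp:
        return vpeak * tau / ramp
    if tau < ramp + plateau:
        return vpeak
    if tau < 2.0 * ramp + plateau:
        return vpeak * (2.0 * ramp + plateau - tau) / ramp
    return 0.0


def gastric_emptied_mass(event: ChallengeEvent, p: PatientParams,
                         t: float) -> float:
    """Cumulative mass (mg) emptied from the stomach by time t (min)."""
    if event.kind not in MEAL_KINDS:
        return 0.0
    tau = t - event.t_start
    if tau <= 0.0:
        return 0.0
    vpeak, ramp, plateau = _gastric_profile(event, p)
    if tau < ramp:
        return 0.5 * vpeak * tau * tau / ramp
    out = 0.5 * vpeak * ramp
    if tau < ramp + plateau:
        return out + vpeak * (tau - ramp)
    out += vpeak * plateau
    rem = min(tau - ramp - plateau, ramp)
    return out + vpeak * rem - 0.5 * vpeak * rem * rem / ramp


def gut_absorption_flux(Ggut: float, p: PatientParams) -> float:
    """Gut -> blood glucose flux (mg/min), saturating in gut content."""
    if Ggut <= 0.0:
        return 0.0
    return p.gut_absorption_vmax * Ggut / (p.gut_absorption_half + Ggut)


def gut_absorption(state: PatientState, p: PatientParams) -> float:
    """Systemic glucose appearance G_in (mg/dL/h) from the gut."""
    return 60.0 * gut_absorption_flux(state.Ggut, p) / p.glucose_volume_dl


def peripheral_utilization(G: float, I_eq: float, p: PatientParams) -> float:
    """Total peripheral glucose utilization G_out (mg/kg/h).

    Insulin-independent uptake (CNS, red cells) plus an insulin-dependent
    term linear in active insulin with slope c (scaled by Sp) and a
    Michaelis-type dependence on glycemia, normalized to 1 at glucose_ref.
    """
    mich = (G * (p.glucose_michaelis_km + p.glucose_ref)
            / (p.glucose_ref * (p.glucose_michaelis_km + G))) if G > 0 else 0.0
    dependent = 60.0 * p.c * (p.Sp / p.sp_ref) * max(I_eq, 0.0) * mich
    return p.insulin_independent_util + dependent


def net_hepatic_glucose_balance(G: float, I: float, p: PatientParams) -> float:
    """NHGB (mg/h): hepatic production minus uptake.

    Piecewise-linear and non-increasing in effective insulin Sh*I, with a
    linear glucose correction, clipped to the configured table endpoints.
    """
    table = p.nhgb_table
    x = p.Sh * max(I, 0.0)
    xs = [row[0] for row in table]
    i = bisect_right(xs, x)
    if i <= 0:
        base = table[0][1]
    elif i >= len(table):
        base = table[-1][1]
    else:
        x0, y0 = table[i - 1]
        x1, y1 = table[i]
        base = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    dg = p.glucose_ref - G
    slope = p.nhgb_hypo_slope if dg > 0 else p.nhgb_glucose_slope
    value = base + slope * dg
    if G < p.nhgb_rescue_threshold:
        # counter-regulatory hormones respond steeply to frank hypoglycemia
        value += p.nhgb_rescue_slope * (p.nhgb_rescue_threshold - G)
    lo = min(table[0][1], table[-1][1])
    hi = max(table[0][1], table[-1][1])
    # liver output scales with body size (table is referenced to 70 kg)
    return min(max(value, lo), hi) * (p.body_weight / p.nhgb_weight_ref)


def renal_excretion(G: float, p: PatientParams) -> float:
    """Renal glucose excretion G_ren (mg/h), linear above the threshold."""
    if G <= p.renal_threshold:
        return 0.0
    return p.renal_clearance * (G - p.renal_threshold)


def insulin_kinetics(I: float, Ia: float, infusion: float,
                     p: PatientParams, I_action: float | None = None
                     ) -> tuple[float, float]:
    """(dI/dt, dIa/dt) in mIU/L/min for a total IV input `infusion` (mIU/min).

    I_action is the plasma insulin seen by the active pool (plasma plus any
    analytically-tracked bolus contribution); defaults to I.
    """
    if infusion < 0:
        raise ValueError("insulin infusion rate must be >= 0")
    k_build, k_decay = p.active_insulin_rates
    dI = infusion / p.insulin_dist_volume - p.insulin_elim_rate * I
    dIa = k_build * (I if I_action is None else I_action) - k_decay * Ia
    return dI, dIa


def bolus_eigenrates(m: BolusInsulinModel) -> tuple[float, float]:
    """Fast/slow exponents (1/min) of the two-compartment bolus model."""
    s = m.k12 + m.k21 + m.k_el
    disc = math.sqrt(s * s - 4.0 * m.k21 * m.k_el)
    return (s + disc) / 2.0, (s - disc) / 2.0


def iv_insulin_bolus(dose: float, t_since: float, m: BolusInsulinModel) -> float:
    """Central-compartment insulin contribution (mIU/L) of an IV bolus.

    dose in IU; biexponential decay with c(0) = dose/V1 and
    AUC = dose/(k_el*V1).
    """
    if dose <= 0:
        raise InvalidEventError("bolus dose must be > 0")
    if t_since < 0.0:
        return 0.0
    lam1, lam2 = bolus_eigenrates(m)
    a1 = (lam1 - m.k21) / (lam1 - lam2)
    a2 = (m.k21 - lam2) / (lam1 - lam2)
    return (dose * 1000.0 / m.V1) * (a1 * math.exp(-lam1 * t_since)
                                     + a2 * math.exp(-lam2 * t_since))


def glucose_balance(G_in: float, NHGB: float, G_out: float, G_ren: float,
                    iv_glucose: float, p: PatientParams) -> float:
    """dG/dt (mg/dL/h) from the four fluxes plus IV glucose (mg/min)."""
    v = p.glucose_volume_dl
    return (G_in + (NHGB - G_ren + 60.0 * iv_glucose) / v
            - G_out * p.body_weight / v)


class VirtualPatient:
    """Integrates the patient ODEs under pump infusions and challenge events."""

    def __init__(self, params: PatientParams,
                 bolus_model: BolusInsulinModel | None = None,
                 events: list[ChallengeEvent] | None = None):
        self.p = params.validate()
        self.bolus_model = (bolus_model or BolusInsulinModel()).validate()
        self.events = sorted(events or [], key=lambda e: e.t_start)
        self._meals = [e for e in self.events if e.kind in MEAL_KINDS]
        self._glc_boluses = [e for e in self.events if e.kind == "iv_glucose_bolus"]
        self._ins_boluses = [e for e in self.events if e.kind == "iv_insulin_bolus"]
        self._clip_warned = False

    # ---- event-driven inputs --------------------------------------------

    def meal_emptying(self, t: float) -> float:
        """Total stomach->gut flux (mg/min) from all meals at time t."""
        s = PatientState(t=t)
        return sum(gastric_emptying_flux(s, e, self.p) for e in self._meals)

    def stomach_mass(self, t: float) -> float:
        """Carbohydrate mass (mg) still in the stomach at time t."""
        total = 0.0
        for e in self._meals:
            if t > e.t_start:
                total += e.amount * 1000.0 - gastric_emptied_mass(e, self.p, t)
        return max(total, 0.0)

    def iv_glucose_rate(self, t: float) -> float:
        """IV dextrose challenge flux (mg/min) at time t."""
        rate = 0.0
        for e in self._glc_boluses:
            dur = max(e.duration, 1e-9)
            if e.t_start <= t < e.t_start + dur:
                rate += e.amount * 1000.0 / dur
        return rate

    def bolus_insulin(self, t: float) -> float:
        """Analytic plasma-insulin contribution (mIU/L) of IV insulin boluses."""
        total = 0.0
        for e in self._ins_boluses:
            # the 2-s push is treated as an instantaneous dose at its midpoint
            total += iv_insulin_bolus(e.amount, t - e.t_start - 0.5 * e.duration,
                                      self.bolus_model) if t >= e.t_start else 0.0
        return total

    # ---- ODE right-hand side --------------------------------------------

    def derivatives(self, t: float, y: tuple[float, float, float, float],
                    insulin_infusion: float, glucose_infusion: float
                    ) -> tuple[float, float, float, float]:
        """d/dt of (G, I, Ia, Ggut); infusions in mIU/min and mg/min."""
        G, I, Ia, Ggut = y
        p = self.p
        f_abs = gut_absorption_flux(Ggut, p)
        g_in = 60.0 * f_abs / p.glucose_volume_dl
        I_total = I + self.bolus_insulin(t)
        nhgb = net_hepatic_glucose_balance(G, I_total, p)
        g_out = peripheral_utilization(G, Ia, p)
        g_ren = renal_excretion(G, p)
        iv_glc = glucose_infusion + self.iv_glucose_rate(t)
        dG = glucose_balance(g_in, nhgb, g_out, g_ren, iv_glc, p) / 60.0
        dI, dIa = insulin_kinetics(I, Ia, insulin_infusion, p, I_action=I_total)
        dGgut = self.meal_emptying(t) - f_abs
        return dG, dI, dIa, dGgut

    def step(self, state: PatientState, insulin_infusion: float,
             glucose_infusion: float, dt: float) -> PatientState:
        """Advance one RK4 step of length dt (min) with inputs held constant."""
        if not dt > 0:
            raise ValueError("dt must be > 0")
        t, y = state.t, (state.G, state.I, state.Ia, state.Ggut)

        def f(tt, yy):
            return self.derivatives(tt, yy, insulin_infusion, glucose_infusion)

        k1 = f(t, y)
        k2 = f(t + dt / 2, tuple(a + dt / 2 * b for a, b in zip(y, k1)))
        k3 = f(t + dt / 2, tuple(a + dt / 2 * b for a, b in zip(y, k2)))
        k4 = f(t + dt, tuple(a + dt * b for a, b in zip(y, k3)))
        new = [a + dt / 6.0 * (b + 2 * c + 2 * d + e)
               for a, b, c, d, e in zip(y, k1, k2, k3, k4)]
        for name, v in zip(("G", "I", "Ia", "Ggut"), new):
            if not math.isfinite(v):
                raise IntegrationError(
                    f"state variable '{name}' became non-finite at t={t + dt:.3f} min")
        if any(v < 0.0 for v in new):
            if not self._clip_warned:
                log.warning("negative state clipped to 0 at t=%.2f min "
                            "(physiological floor)", t + dt)
                self._clip_warned = True
            new = [max(v, 0.0) for v in new]
        return PatientState(G=new[0], I=new[1], Ia=new[2], Ggut=new[3],
                            Gstomach=self.stomach_mass(t + dt), t=t + dt)

    def steady_insulin(self, infusion: float) -> float:
        """Closed-form steady-state plasma insulin (mIU/L) for constant infusion."""
        return infusion / (self.insulin_clearance)

    @property
    def insulin_clearance(self) -> float:
        """k_el * V_I (L/min): plasma insulin clearance."""
        return self.p.insulin_elim_rate * self.p.insulin_dist_volume


__all__ = [
    "ChallengeEvent", "PatientState", "VirtualPatient",
    "InvalidEventError", "IntegrationError",
    "gastric_emptying_flux", "gastric_emptied_mass", "gut_absorption",
    "gut_absorption_flux", "peripheral_utilization",
    "net_hepatic_glucose_balance", "renal_excretion", "insulin_kinetics",
    "iv_insulin_bolus", "bolus_eigenrates", "glucose_balance",
    "MEAL_KINDS", "EVENT_KINDS",
]
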