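"""The AIIS control law, executed once per 5-minute sensor reading.

Insulin: a proportional-derivative law built from a hyperbolic tangent,
    IR' = (M/2) * (1 + tanh(S_slope * (G0 + DF - B)))        [mIU/min]
where the differential factor DF = K2*A / sqrt(1 + K1*A^2) is an odd,
saturating function of the glycemia trend A = a0*G0 + a5*G5 + a10*G10.
Glucose rescue: proportional, GR' = K_G * max(0, G_crit - G0)  [mL/h].
Emergency logic: when the last reading falls below G_crit the insulin line
drops to its minimum (KVO) and the glucose line activates; normal operation
resumes at the first reading back above G_crit.

The controller works in mIU/min internally; conversion to pump mL/h happens
at the pump boundary (see `aiis.pumps`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ControllerParams
from .sensor import SensorReading


class SequencingError(RuntimeError):
    """Readings delivered out of chronological order."""


@dataclass
class GlucoseHistory:
    """The last three 5-min glycemia readings (None during warm-up)."""

    G0: float | None = None
    G5: float | None = None
    G10: float | None = None

    @property
    def full(self) -> bool:
        return None not in (self.G0, self.G5, self.G10)

    def push(self, reading: float) -> None:
        self.G10, self.G5, self.G0 = self.G5, self.G0, reading


@dataclass
class ControllerOutput:
    IR: float               # mIU/min, insulin rate commanded after emergency logic
    IR_prime: float         # mIU/min, raw insulin-controller rate
    GR: float               # mL/h, glucose rate commanded after emergency logic
    GR_prime: float         # mL/h, raw glucose-controller rate
    emergency_active: bool
    A: float = 0.0          # mg/dL, trend parameter
    DF: float = 0.0         # mg/dL, differential factor


def diff_parameter_A(h: GlucoseHistory, p: ControllerParams) -> float:
    """Trend parameter A (mg/dL); zero during the warm-up of the history."""
    if not h.full:
        return 0.0
    return p.a0 * h.G0 + p.a5 * h.G5 + p.a10 * h.G10


def diff_factor_DF(A: float, p: ControllerParams) -> float:
    """Differential factor (mg/dL): odd in A, saturating at K2/sqrt(K1)."""
    return p.K2 * A / math.sqrt(1.0 + p.K1 * A * A)


def insulin_infusion_law(G0: float, DF: float, p: ControllerParams) -> float:
    """Raw insulin rate IR' (mIU/min) from the tanh PD law."""
    return 0.5 * p.M * (1.0 + math.tanh(p.S_slope * (G0 + DF - p.B)))


def glucose_infusion_law(G0: float, p: ControllerParams) -> float:
    """Raw glucose-rescue rate GR' (mL/h), proportional below G_crit."""
    return p.K_G * max(0.0, p.G_crit - G0)


def emergency_logic(G0: float, IR_prime: float, GR_prime: float,
                    p: ControllerParams) -> tuple[float, float, bool]:
    """(IR, GR, emergency_active): mutual exclusion of the two lines."""
    if G0 < p.G_crit:
        return p.IR_min, GR_prime, True
    return max(IR_prime, p.IR_min), 0.0, False


class AiisController:
    """Stateful controller invoked exactly once per emitted sensor reading."""

    def __init__(self, params: ControllerParams):
        self.p = params.validate()
        self.history = GlucoseHistory()
        self._last_t: float | None = None

    def step(self, reading: SensorReading) -> ControllerOutput:
        if self._last_t is not None and reading.t <= self._last_t:
            raise SequencingError(
                f"reading at t={reading.t} min is not after t={self._last_t} min")
        self._last_t = reading.t
        self.history.push(reading.G_est)
        A = diff_parameter_A(self.history, self.p)
        DF = diff_factor_DF(A, self.p)
        G0 = self.history.G0
        IR_prime = insulin_infusion_law(G0, DF, self.p)
        GR_prime = glucose_infusion_law(G0, self.p)
        IR, GR, emergency = emergency_logic(G0, IR_prime, GR_prime, self.p)
        return ControllerOutput(IR=IR, IR_prime=IR_prime, GR=GR,
                                GR_prime=GR_prime, emergency_active=emergency,
                                A=A, DF=DF)


__all__ = [
    "AiisController", "ControllerOutput", "GlucoseHistory", "SequencingError",
    "diff_parameter_A", "diff_factor_DF", "insulin_infusion_law",
    "glucose_infusion_law", "emergency_logic",
]
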