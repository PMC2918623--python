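"""Volumetric infusion-pump actuator model (IMED Gemini PC-1 constraints).

Commanded rates are quantized to the pump's 0.1 mL/h steps (ties round
half-up) and clamped to [rate_min, rate_max] while the line is active.  The
insulin line is never allowed below the keep-vein-open rate; the glucose
line delivers zero between emergencies.  `delivered_dose` is the exact unit
bridge between the pump's mL/h and the physiological fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import PumpSpec


def quantize_rate(requested: float, spec: PumpSpec, active: bool = True,
                  is_insulin_line: bool = False) -> float:
    """Delivered rate (mL/h) for a requested rate on one pump line."""
    if requested < 0:
        raise ValueError("requested rate must be >= 0")
    if not active:
        return spec.kvo_rate if is_insulin_line else 0.0
    n = math.floor(requested / spec.rate_step + 0.5)  # round half-up
    rate = n * spec.rate_step
    return min(max(rate, spec.rate_min), spec.rate_max)


def delivered_dose(rate: float, spec: PumpSpec) -> float:
    """Drug flux per minute for a delivered rate: rate [mL/h] x concentration.

    Insulin line (concentration IU/mL): returns mIU/min.
    Glucose line (concentration mg/mL): returns mg/min.
    """
    per_hour = rate * spec.concentration           # IU/h or mg/h
    return per_hour * (1000.0 / 60.0) if _is_insulin(spec) else per_hour / 60.0


def _is_insulin(spec: PumpSpec) -> bool:
    # Insulin solutions are ~1 IU/mL; dextrose solutions are hundreds of
    # mg/mL.  The line identity is carried by the InfusionPump wrapper; this
    # fallback only serves direct calls on a bare spec.
    return spec.concentration < 50.0


@dataclass
class InfusionPump:
    """One pump line with its solution concentration and drug identity."""

    spec: PumpSpec
    drug: str  # "insulin" or "glucose"

    def __post_init__(self) -> None:
        if self.drug not in ("insulin", "glucose"):
            raise ValueError("drug must be 'insulin' or 'glucose'")
        self.spec.validate()

    def command_mlh(self, requested_mlh: float, active: bool = True) -> float:
        """Quantized/clamped delivered rate (mL/h)."""
        return quantize_rate(requested_mlh, self.spec, active=active,
                             is_insulin_line=self.drug == "insulin")

    def rate_from_insulin_flux(self, mIU_per_min: float) -> float:
        """mL/h equivalent of a commanded insulin flux (mIU/min)."""
        iu_per_h = mIU_per_min * 60.0 / 1000.0
        return iu_per_h / self.spec.concentration

    def flux(self, delivered_mlh: float) -> float:
        """Drug flux of a delivered rate: mIU/min (insulin) or mg/min (glucose)."""
        per_hour = delivered_mlh * self.spec.concentration
        if self.drug == "insulin":
            return per_hour * 1000.0 / 60.0   # IU/h -> mIU/min
        return per_hour / 60.0                # mg/h -> mg/min


__all__ = ["quantize_rate", "delivered_dose", "InfusionPump"]
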