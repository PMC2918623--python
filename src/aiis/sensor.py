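"""Subcutaneous CGM model: first-order lag, gain, noise, averaging, saturation.

The sensor current S (nA) follows dS/dt = (alpha*G(t - T_D) - S)/tau.  The
current is sampled every `sample_period` seconds, each raw sample corrupted
with white Gaussian noise, and every `averaging_window` minutes the buffered
samples are averaged, divided by the gain alpha and clamped to the
[sat_low, sat_high] reporting range to produce one glucose estimate.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .params import SensorParams


@dataclass
class SensorReading:
    t: float       # min
    G_est: float   # mg/dL, 5-min averaged, saturated estimate


@dataclass
class SensorState:
    S: float                       # nA, lagged sensor current
    buffer: list = field(default_factory=list)  # raw noisy samples (nA)
    last_reading_time: float = 0.0  # min


class CgmsSensor:
    """Discrete-time simulation of the subcutaneous sensor.

    `update_and_sample` must be called once per raw sampling interval with
    the current true glycemia; the lag ODE is advanced with its exact
    zero-order-hold solution, so a step in G reaches 63.2% of its
    equilibrium change at t = tau regardless of the sampling rate.
    """

    def __init__(self, params: SensorParams, rng: np.random.Generator | None = None,
                 initial_G: float = 100.0):
        self.p = params.validate()
        self.rng = rng if rng is not None else np.random.default_rng()
        self.state = SensorState(S=self.p.alpha * initial_G)
        self._dt_min = self.p.sample_period / 60.0
        self._decay = math.exp(-self._dt_min / self.p.tau)
        self._delay_steps = round(self.p.T_D / self._dt_min) if self.p.T_D > 0 else 0
        if self._delay_steps and abs(self._delay_steps * self._dt_min - self.p.T_D) > 1e-9:
            raise ValueError("T_D must be a multiple of the raw sampling interval")
        self._delay_line: deque = deque([initial_G] * (self._delay_steps + 1),
                                        maxlen=self._delay_steps + 1)
        self._noise_sd = math.sqrt(self.p.noise_variance)

    # ---- continuous dynamics --------------------------------------------

    def dynamics(self, S: float, G_delayed: float) -> float:
        """dS/dt (nA/min) of the first-order lag."""
        return (self.p.alpha * G_delayed - S) / self.p.tau

    def advance(self, G_now: float) -> float:
        """Advance the lag ODE one raw sampling interval; returns S (nA)."""
        self._delay_line.append(G_now)
        G_used = self._delay_line[0]
        s_inf = self.p.alpha * G_used
        self.state.S = s_inf + (self.state.S - s_inf) * self._decay
        return self.state.S

    # ---- sampling & reporting -------------------------------------------

    def sample_raw(self) -> float:
        """One noisy raw sample (nA) of the current sensor signal."""
        eps = self.rng.normal(0.0, self._noise_sd) if self._noise_sd > 0 else 0.0
        sample = self.state.S + eps
        self.state.buffer.append(sample)
        return sample

    def emit_reading(self, t: float) -> SensorReading | None:
        """Average the window into a glucose estimate; None until full."""
        n = self.p.samples_per_reading
        if len(self.state.buffer) < n:
            return None
        mean_nA = sum(self.state.buffer) / len(self.state.buffer)
        self.state.buffer = []
        self.state.last_reading_time = t
        g = mean_nA / self.p.alpha
        g = min(max(g, self.p.sat_low), self.p.sat_high)
        return SensorReading(t=t, G_est=g)

    def update_and_sample(self, t: float, G_now: float) -> SensorReading | None:
        """Advance one sampling interval, store a noisy sample, maybe report."""
        self.advance(G_now)
        self.sample_raw()
        if len(self.state.buffer) >= self.p.samples_per_reading:
            return self.emit_reading(t)
        return None


__all__ = ["CgmsSensor", "SensorReading", "SensorState"]
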