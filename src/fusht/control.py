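"""Relay (bang-bang) temperature control with hysteresis.

Emulates the experimental regulation loop: a PID box gating a function
generator ON below the target temperature and OFF above it. The simulated
equivalent is an ideal two-state relay — the source is disabled when the
sensor temperature *exceeds* the upper threshold (42 °C by default) and
re-enabled when it *falls below* the lower threshold (41.5 °C); inside the
band the previous state is kept, so the band acts as switching memory and
prevents chattering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HysteresisController"]


@dataclass
class HysteresisController:
    """Two-threshold ON/OFF relay.

    Parameters
    ----------
    upper, lower : float
        Switch-off and switch-on thresholds, °C; ``lower < upper``.
    state : bool
        Current source state; treatment starts with the source ON.
    sensor_index : tuple of int, optional
        Grid voxel whose temperature the relay reads (tumor centre by
        convention); stored here so the solver knows where to probe.
    """

    upper: float = 42.0
    lower: float = 41.5
    state: bool = True
    sensor_index: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower threshold must be below upper threshold")

    def update(self, sensor_temperature: float) -> bool:
        """Advance the relay one observation; returns the new state.

        Strict comparisons: ON→OFF exactly when T > upper, OFF→ON exactly
        when T < lower, otherwise unchanged.
        """
        t = float(sensor_temperature)
        if not np.isfinite(t):
            raise ValueError("sensor temperature must be finite")
        if self.state and t > self.upper:
            self.state = False
        elif not self.state and t < self.lower:
            self.state = True
        return self.state

    def reset(self, state: bool = True) -> None:
        self.state = state
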