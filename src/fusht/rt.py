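"""Radiotherapy beam-on time planning for a small-animal irradiator.

Beam-on time is prescribed dose divided by the effective dose rate — the
machine's base output rate scaled by the collimator output factor (the
ratio of the collimated to open-field rate; ~0.79 for the 5 mm cone of a
SARRP-class platform). A percent-depth-dose hook is provided as an extra
multiplicative factor on the rate, defaulting to 1 since the shallow
(~3 mm) subcutaneous target makes the depth correction negligible at the
reported rounding; the target depth is carried as plan metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RTPlan", "beam_on_time"]

DEFAULT_BASE_RATE = 4.1  # Gy/min
DEFAULT_OUTPUT_FACTOR = 0.79  # 5 mm collimator


def beam_on_time(
    dose: float,
    base_rate: float = DEFAULT_BASE_RATE,
    output_factor: float = DEFAULT_OUTPUT_FACTOR,
    depth_dose_factor: float = 1.0,
) -> float:
    """Beam-on time in minutes: dose / (base_rate × OF × PDD).

    All inputs must be positive; the output factor cannot exceed 1.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if not 0 < output_factor <= 1:
        raise ValueError("output_factor must lie in (0, 1]")
    if depth_dose_factor <= 0:
        raise ValueError("depth_dose_factor must be positive")
    return dose / (base_rate * output_factor * depth_dose_factor)


@dataclass(frozen=True)
class RTPlan:
    """One-field plan: prescription, machine factors, computed time."""

    dose: float  # Gy
    base_rate: float = DEFAULT_BASE_RATE  # Gy/min
    output_factor: float = DEFAULT_OUTPUT_FACTOR
    target_depth_mm: float = 3.0  # informational
    depth_dose_factor: float = 1.0

    def __post_init__(self) -> None:
        # beam_on_time validates all numeric constraints
        beam_on_time(self.dose, self.base_rate, self.output_factor,
                     self.depth_dose_factor)

    @property
    def beam_on_min(self) -> float:
        """Exact beam-on time, minutes."""
        return beam_on_time(self.dose, self.base_rate, self.output_factor,
                            self.depth_dose_factor)

    @property
    def beam_on_min_rounded(self) -> float:
        """Beam-on time rounded to 0.1 min, as set on the console."""
        return round(self.beam_on_min, 1)

    def describe(self) -> str:
        return (
            f"{self.dose:g} Gy @ {self.base_rate:g} Gy/min x OF "
            f"{self.output_factor:g} -> {self.beam_on_min:.3f} min "
            f"(console: {self.beam_on_min_rounded:.1f} min)"
        )
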