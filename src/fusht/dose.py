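"""CEM43 thermal dose: cumulative equivalent minutes at 43 °C.

Dose for a piecewise-constant temperature history is
``CEM43 = Σ_i Δt_i[min] · R^(43 − T_i)`` with the Sapareto–Dewey rate
constants R = 0.50 at or above the 43 °C breakpoint and R = 0.25 below it.
A constant 43 °C exposure therefore accrues exactly one equivalent minute
per minute; 42 °C accrues a quarter of that, and each further degree below
divides by four again.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids import SimulationGrid

__all__ = ["ThermalDoseMap", "Cem43Accumulator", "cem43", "max_cem43",
           "R_ABOVE_DEFAULT", "R_BELOW_DEFAULT", "BREAKPOINT_C"]

R_ABOVE_DEFAULT = 0.50
R_BELOW_DEFAULT = 0.25
BREAKPOINT_C = 43.0


@dataclass
class ThermalDoseMap:
    """Per-voxel CEM43 (equivalent minutes at 43 °C)."""

    grid: SimulationGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        if self.dose.shape != tuple(self.grid.shape):
            raise ValueError("dose shape does not match grid")
        if np.any(self.dose < 0):
            raise ValueError("thermal dose must be non-negative")


def _increment(T: np.ndarray, dt_s: float, r_above: float, r_below: float) -> np.ndarray:
    r = np.where(T >= BREAKPOINT_C, r_above, r_below)
    return (dt_s / 60.0) * r ** (BREAKPOINT_C - T)


class Cem43Accumulator:
    """Streaming CEM43 integrator for long runs.

    Feed temperature snapshots as they are produced (e.g. from the bioheat
    driver's snapshot hook) instead of storing the full field history.
    """

    def __init__(self, grid: SimulationGrid,
                 r_above: float = R_ABOVE_DEFAULT,
                 r_below: float = R_BELOW_DEFAULT):
        if not (0 < r_below <= 1 and 0 < r_above <= 1):
            raise ValueError("R constants must lie in (0, 1]")
        self.grid = grid
        self.r_above = r_above
        self.r_below = r_below
        self._dose = np.zeros(tuple(grid.shape))

    def add(self, temperature: np.ndarray, dt_s: float) -> None:
        """Accrue ``dt_s`` seconds at the given temperature field."""
        if dt_s < 0:
            raise ValueError("dt must be non-negative")
        if temperature.shape != self._dose.shape:
            raise ValueError("temperature shape does not match grid")
        self._dose += _increment(temperature, dt_s, self.r_above, self.r_below)

    @property
    def map(self) -> ThermalDoseMap:
        return ThermalDoseMap(grid=self.grid, dose=self._dose.copy())


def cem43(
    snapshots: Sequence[np.ndarray] | np.ndarray,
    dt: float | Sequence[float],
    grid: SimulationGrid | None = None,
    r_above: float = R_ABOVE_DEFAULT,
    r_below: float = R_BELOW_DEFAULT,
) -> ThermalDoseMap:
    """CEM43 map from a sequence of temperature snapshots.

    Each snapshot is held piecewise-constant for its interval: a scalar
    ``dt`` applies to every snapshot, or pass one interval per snapshot.
    Snapshots may be full fields or scalars/1-D sensor traces (then
    ``grid`` defaults to a single-voxel grid).
    """
    snaps = [np.asarray(s, dtype=np.float64) for s in snapshots]
    if not snaps:
        raise ValueError("history is empty")
    if np.isscalar(dt):
        if dt < 0:
            raise ValueError("dt must be non-negative")
        dts = [float(dt)] * len(snaps)
    else:
        dts = [float(d) for d in dt]
        if len(dts) != len(snaps):
            raise ValueError("one interval per snapshot required")
        if any(d < 0 for d in dts):
            raise ValueError("dt must be non-negative")

    shape = snaps[0].shape if snaps[0].ndim else (1,)
    if grid is None:
        g3 = shape + (1,) * (3 - len(shape)) if len(shape) < 3 else shape
        grid = SimulationGrid((1e-3, 1e-3, 1e-3), tuple(int(n) for n in g3))
    acc = Cem43Accumulator(grid, r_above=r_above, r_below=r_below)
    gshape = tuple(grid.shape)
    for s, d in zip(snaps, dts):
        acc.add(s.reshape(gshape) if s.shape != gshape else s, d)
    return acc.map


def max_cem43(dose_map: ThermalDoseMap, mask: np.ndarray | None = None) -> float:
    """Maximum dose over a region (whole grid when ``mask`` is None)."""
    if mask is None:
        return float(dose_map.dose.max())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose_map.dose.shape:
        raise ValueError("mask shape does not match dose map")
    if not mask.any():
        raise ValueError("region mask is empty")
    return float(dose_map.dose[mask].max())
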