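"""Regular Cartesian simulation grids.

Axis convention: ``z`` is the acoustic propagation axis with the transducer
apex at ``z = 0``; ``x`` and ``y`` are lateral axes centred on the beam axis.
Voxel *centres* are the sample points: the axial coordinate of voxel ``k`` is
``k * dz`` and lateral voxel counts are kept odd so that the beam axis
(x = y = 0) passes exactly through a column of voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimulationGrid"]


@dataclass(frozen=True)
class SimulationGrid:
    """Voxel grid on which acoustic and thermal fields are sampled.

    Parameters
    ----------
    spacing : tuple of float
        Voxel spacing per axis (dx, dy, dz), metres.
    shape : tuple of int
        Voxel counts per axis (nx, ny, nz).
    """

    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("spacing and shape must have three entries")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(int(n) < 1 or int(n) != n for n in self.shape):
            raise ValueError("grid shape must be positive integers")

    @classmethod
    def from_extent(
        cls,
        spacing_m: float,
        lateral_extent_m: float,
        axial_extent_m: float,
    ) -> "SimulationGrid":
        """Build a grid covering the requested physical extents.

        Lateral counts are rounded up to odd so the axis lies on voxel
        centres; the axial extent starts at the transducer apex (z = 0).
        """
        nlat = int(round(lateral_extent_m / spacing_m)) + 1
        if nlat % 2 == 0:
            nlat += 1
        nz = int(round(axial_extent_m / spacing_m)) + 1
        return cls((spacing_m, spacing_m, spacing_m), (nlat, nlat, nz))

    @property
    def x(self) -> np.ndarray:
        nx = self.shape[0]
        return (np.arange(nx) - (nx - 1) / 2) * self.spacing[0]

    @property
    def y(self) -> np.ndarray:
        ny = self.shape[1]
        return (np.arange(ny) - (ny - 1) / 2) * self.spacing[1]

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.shape[2]) * self.spacing[2]

    @property
    def axis_index(self) -> tuple[int, int]:
        """(i, j) lateral indices of the beam axis column."""
        return (self.shape[0] - 1) // 2, (self.shape[1] - 1) // 2

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def nearest_voxel(self, point_m: tuple[float, float, float]) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to a physical point."""
        idx = (
            int(round(point_m[0] / self.spacing[0] + (self.shape[0] - 1) / 2)),
            int(round(point_m[1] / self.spacing[1] + (self.shape[1] - 1) / 2)),
            int(round(point_m[2] / self.spacing[2])),
        )
        if not all(0 <= idx[a] < self.shape[a] for a in range(3)):
            raise ValueError(f"point {point_m} lies outside the grid")
        return idx
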