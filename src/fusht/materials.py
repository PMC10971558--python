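"""Tissue media, layered phantom geometry, and voxelised material maps.

The default property table describes the four media of the treatment scene —
coupling water, rat skin, subcutaneous C6 tumor, and muscle background.
Attenuation is stored in Np/(m·MHz) and assumed linear in frequency;
perfusion is a volumetric blood mass flow in kg/(m³·s) feeding the Pennes
perfusion sink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import SimulationGrid

__all__ = [
    "Medium",
    "DEFAULT_MEDIA",
    "WATER",
    "SKIN",
    "TUMOR",
    "MUSCLE",
    "LayeredPhantom",
    "MaterialMap",
    "build_material_map",
]


@dataclass(frozen=True)
class Medium:
    """Acoustic + thermal + perfusion properties of one tissue type."""

    name: str
    density: float  # kg/m^3
    sound_speed: float  # m/s
    attenuation: float  # Np/(m*MHz)
    conductivity: float  # W/(m*degC)
    specific_heat: float  # J/(kg*degC)
    perfusion: float  # kg/(m^3*s)

    def __post_init__(self) -> None:
        for f in ("density", "sound_speed", "attenuation", "conductivity",
                  "specific_heat", "perfusion"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be non-negative")


WATER = Medium("water", 1000.0, 1482.0, 0.0, 0.627, 4118.0, 0.0)
SKIN = Medium("skin", 1060.0, 1624.0, 21.2, 0.5, 3700.0, 2.0)
TUMOR = Medium("tumor", 1060.0, 1560.0, 9.32, 0.5, 3700.0, 20.0)
MUSCLE = Medium("muscle", 1060.0, 1588.0, 7.1, 0.52, 3700.0, 0.7)

DEFAULT_MEDIA: dict[str, Medium] = {
    m.name: m for m in (WATER, SKIN, TUMOR, MUSCLE)
}

# integer labels used in MaterialMap.medium_id
MEDIUM_IDS = {"water": 0, "skin": 1, "tumor": 2, "muscle": 3}


@dataclass(frozen=True)
class LayeredPhantom:
    """Water / skin / tumor-in-muscle geometry along the beam axis.

    ``water_standoff`` is the apex-to-skin distance. By default the tumor
    centre sits at the transducer's geometric focus and the standoff is
    chosen so the tumor's proximal pole touches the deep side of the skin
    (tumor "just beneath" the skin).
    """

    water_standoff: float  # m, apex to skin surface
    skin_thickness: float = 0.8e-3  # m
    tumor_diameter: float = 6.0e-3  # m
    tumor_center: tuple[float, float, float] | None = None  # m; None -> on axis at
    # water_standoff + skin + tumor radius
    media: dict[str, Medium] = field(default_factory=lambda: dict(DEFAULT_MEDIA))

    def __post_init__(self) -> None:
        if self.skin_thickness <= 0:
            raise ValueError("skin_thickness must be positive")
        if self.water_standoff < 0:
            raise ValueError("water_standoff must be non-negative")
        if self.tumor_diameter < 0:
            raise ValueError("tumor_diameter must be non-negative")

    @classmethod
    def default_for_focus(
        cls,
        focal_length: float,
        skin_thickness: float = 0.8e-3,
        tumor_diameter: float = 6.0e-3,
        water_standoff: float | None = None,
    ) -> "LayeredPhantom":
        """Standard scene: tumor centred at the geometric focus.

        Unless given, the water standoff is ``focal_length - skin -
        tumor_radius`` so the tumor's proximal surface meets the skin.
        """
        if water_standoff is None:
            water_standoff = focal_length - skin_thickness - tumor_diameter / 2
        return cls(
            water_standoff=water_standoff,
            skin_thickness=skin_thickness,
            tumor_diameter=tumor_diameter,
            tumor_center=(0.0, 0.0, focal_length),
        )

    def resolved_tumor_center(self) -> tuple[float, float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return (
            0.0,
            0.0,
            self.water_standoff + self.skin_thickness + self.tumor_diameter / 2,
        )


@dataclass
class MaterialMap:
    """Per-voxel material properties on a :class:`SimulationGrid`.

    ``medium_id`` labels each voxel with its source medium
    (0 water, 1 skin, 2 tumor, 3 muscle); the property arrays are what the
    solvers consume, so a map may also be built directly from arrays.
    """

    grid: SimulationGrid
    density: np.ndarray
    sound_speed: np.ndarray
    attenuation: np.ndarray  # Np/(m*MHz)
    conductivity: np.ndarray
    specific_heat: np.ndarray
    perfusion: np.ndarray
    medium_id: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(self.grid.shape)
        for name in ("density", "sound_speed", "attenuation", "conductivity",
                     "specific_heat", "perfusion", "medium_id"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")
            if name != "medium_id" and np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative everywhere")

    @property
    def water_mask(self) -> np.ndarray:
        return self.medium_id == MEDIUM_IDS["water"]

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.medium_id == MEDIUM_IDS["tumor"]

    @classmethod
    def uniform(cls, grid: SimulationGrid, medium: Medium,
                medium_id: int = 3) -> "MaterialMap":
        """Homogeneous map of a single medium (handy for water-only runs)."""
        shape = tuple(grid.shape)

        def full(v: float) -> np.ndarray:
            return np.full(shape, v, dtype=np.float64)

        return cls(
            grid=grid,
            density=full(medium.density),
            sound_speed=full(medium.sound_speed),
            attenuation=full(medium.attenuation),
            conductivity=full(medium.conductivity),
            specific_heat=full(medium.specific_heat),
            perfusion=full(medium.perfusion),
            medium_id=np.full(shape, medium_id, dtype=np.int8),
        )


def build_material_map(phantom: LayeredPhantom, grid: SimulationGrid) -> MaterialMap:
    """Voxelise a layered phantom onto a grid.

    Layers are assigned by voxel-centre position: water for
    ``z < standoff``, skin for the next ``skin_thickness``, muscle beyond,
    and tumor inside the sphere at the configured centre. Deterministic:
    the same phantom and grid always yield the same map.
    """
    media = phantom.media
    cx, cy, cz = phantom.resolved_tumor_center()
    r_t = phantom.tumor_diameter / 2

    z = grid.z
    skin_top = phantom.water_standoff
    skin_bot = phantom.water_standoff + phantom.skin_thickness

    if r_t > 0:
        if cz - r_t < skin_bot - 1e-12:
            raise ValueError("tumor must lie fully below the skin layer")
        zmax = z[-1] if len(z) else 0.0
        if cz + r_t > zmax:
            raise ValueError("tumor extends beyond the axial grid extent")
        if abs(cx) + r_t > grid.x[-1] or abs(cy) + r_t > grid.y[-1]:
            raise ValueError("tumor extends beyond the lateral grid extent")

    ids = np.full(tuple(grid.shape), MEDIUM_IDS["muscle"], dtype=np.int8)
    ids[:, :, z < skin_top] = MEDIUM_IDS["water"]
    in_skin = (z >= skin_top) & (z < skin_bot)
    ids[:, :, in_skin] = MEDIUM_IDS["skin"]

    if r_t > 0:
        X, Y, Z = np.meshgrid(grid.x, grid.y, z, indexing="ij")
        sphere = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r_t**2
        # tumor only replaces muscle; the geometry check above guarantees
        # the sphere cannot reach water or skin voxels
        ids[sphere] = MEDIUM_IDS["tumor"]

    by_id = {MEDIUM_IDS[name]: media[name] for name in MEDIUM_IDS}
    shape = tuple(grid.shape)

    def lut(attr: str) -> np.ndarray:
        table = np.zeros(max(by_id) + 1)
        for i, m in by_id.items():
            table[i] = getattr(m, attr)
        return table[ids].reshape(shape)

    return MaterialMap(
        grid=grid,
        density=lut("density"),
        sound_speed=lut("sound_speed"),
        attenuation=lut("attenuation"),
        conductivity=lut("conductivity"),
        specific_heat=lut("specific_heat"),
        perfusion=lut("perfusion"),
        medium_id=ids,
    )
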