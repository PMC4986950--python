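"""Flame geometry and convective heat transport.

The model is convection-driven: a burning element produces a flame of some
length tilted from the vertical by wind, and a plume continues along the
flame axis beyond the tip, cooling with distance. The chord this axis cuts
through a crown cross-section (the plume pathway) sets the depth of foliage
that can be heated.

Geometry is two-dimensional in the vertical transect aligned with the
spread direction: x is horizontal (positive downwind), z is height above
ground.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from shapely.geometry import LineString, Point, Polygon

from .config import ModelConfig
from .domain import StratumStructure

G = 9.81  # m/s^2

__all__ = [
    "FlameSegment",
    "PlumePathway",
    "flame_angle",
    "plume_temperature",
    "merged_flame_length",
    "crown_polygon",
    "plume_pathway",
]


@dataclass(frozen=True)
class FlameSegment:
    """One flame: origin height, along-axis length, tilt and temperature."""

    origin_height: float      # m above ground
    flame_length: float       # m along the flame axis
    angle: float              # radians from horizontal, (0, pi/2]
    flame_temperature: float  # degC within the flame zone
    duration_remaining: float  # s of flaming left in the donor

    @property
    def flame_height(self) -> float:
        """Vertical extent: origin + L sin(angle)."""
        return self.origin_height + self.flame_length * math.sin(self.angle)

    @property
    def tip(self) -> tuple[float, float]:
        return (
            self.flame_length * math.cos(self.angle),
            self.origin_height + self.flame_length * math.sin(self.angle),
        )


@dataclass(frozen=True)
class PlumePathway:
    """Chord of the plume axis through a crown cross-section.

    Distances are measured along the axis from the flame origin, so
    ``entry_distance`` locates the crown entry point and
    ``entry_distance + path_length`` the exit.
    """

    entry: tuple[float, float]  # (x, z) of entry, or (nan, nan) on a miss
    exit: tuple[float, float]
    entry_distance: float       # m along the axis from the flame origin
    path_length: float          # m of axis inside the crown; 0 on a miss

    @classmethod
    def miss(cls) -> "PlumePathway":
        nan = float("nan")
        return cls((nan, nan), (nan, nan), 0.0, 0.0)


def flame_angle(
    flame_length: float, wind_speed: float, slope: float, config: ModelConfig
) -> float:
    """Flame angle above horizontal from flame length, wind and slope.

    Vertical (pi/2) in still air on flat ground; tilts over with wind as the
    ratio of buoyant to inertial forces falls (arctan of a Froude-number
    scaling). Ground slope rotates the effective angle: upslope spread
    (positive slope) lays the flame toward the slope, downslope spread
    steepens it. Opposing (negative) wind tilts the flame backwards with the
    same magnitude; the returned angle is measured on the windward side.
    """
    if flame_length < 0:
        raise ValueError("flame_length must be >= 0")
    c = config["flame_angle"]
    u = abs(wind_speed)
    if u == 0:
        base = math.pi / 2
    elif flame_length == 0:
        base = float(c["min_angle_rad"])
    else:
        base = math.atan(float(c["tilt_coeff"]) * math.sqrt(G * flame_length) / u)
    angle = base - float(c["slope_coupling"]) * math.radians(slope)
    if slope != 0:
        # the slope rotation may push the angle out of range; the wind-only
        # arctan is already strictly inside (0, pi/2]
        angle = max(angle, float(c["min_angle_rad"]))
    return float(min(angle, math.pi / 2))


def plume_temperature(
    distance: float, flame: FlameSegment, ambient: float, config: ModelConfig
) -> float:
    """Air temperature (degC) at a distance along the plume axis.

    Constant at the flame temperature within the flame, then the temperature
    excess above ambient decays as a power law of distance, reaching ambient
    in the far field. Never below ambient.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    length = flame.flame_length
    if length <= 0:
        return ambient
    if distance <= length:
        return flame.flame_temperature
    excess = flame.flame_temperature - ambient
    if excess <= 0:
        return ambient
    gamma = float(config["plume"]["decay_exponent"])
    return ambient + excess * (length / distance) ** gamma


def merged_flame_length(
    n_leaves_burning: float, per_leaf_flame: float, config: ModelConfig
) -> float:
    """Flame length from many leaves burning together.

    Zero when nothing burns, the single-leaf flame at n = 1, and grows
    sublinearly (configured merging exponent <= 1) as flames coalesce and
    entrain air.
    """
    if n_leaves_burning < 0:
        raise ValueError("n_leaves_burning must be >= 0")
    if n_leaves_burning == 0:
        return 0.0
    exponent = float(config["flame_merge"]["exponent"])
    return per_leaf_flame * n_leaves_burning ** exponent


def crown_polygon(crown: StratumStructure) -> Polygon:
    """Symmetric cross-section through a plant crown, centred on x = 0.

    Built from the five crown heights and the width: a hexagon with the base
    rising from centre to edge and the top dropping from centre to edge.
    Degenerate inputs (zero area) are rejected.
    """
    half = crown.crown_width / 2.0
    pts = [
        (0.0, crown.crown_base_centre_height),
        (half, crown.crown_base_edge_height),
        (half, crown.crown_top_edge_height),
        (0.0, crown.crown_height),
        (-half, crown.crown_top_edge_height),
        (-half, crown.crown_base_edge_height),
    ]
    poly = Polygon(pts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate crown polygon")
    return poly


_FAR = 1.0e4  # m; ray length that exceeds any site dimension


def plume_pathway(
    flame: FlameSegment, crown: StratumStructure, plant_offset: float = 0.0
) -> PlumePathway:
    """Chord of the plume axis through a crown cross-section.

    The axis is the ray from the flame origin through the flame tip and
    beyond. ``plant_offset`` shifts the crown centre horizontally relative
    to the flame origin. Returns a zero-length pathway when the axis misses
    the crown (e.g. a near-horizontal plume passing under or over it).
    """
    poly = crown_polygon(crown)
    dx, dz = math.cos(flame.angle), math.sin(flame.angle)
    x0, z0 = 0.0, flame.origin_height
    ray = LineString([(x0 - plant_offset, z0), (x0 - plant_offset + dx * _FAR, z0 + dz * _FAR)])
    inter = ray.intersection(poly)
    if inter.is_empty:
        return PlumePathway.miss()
    segments = []
    if inter.geom_type == "LineString":
        segments = [inter]
    elif inter.geom_type == "MultiLineString":
        segments = list(inter.geoms)
    elif inter.geom_type in ("Point", "MultiPoint"):
        return PlumePathway.miss()
    elif inter.geom_type == "GeometryCollection":
        segments = [g for g in inter.geoms if g.geom_type == "LineString"]
        if not segments:
            return PlumePathway.miss()
    total = sum(seg.length for seg in segments)
    if total <= 0:
        return PlumePathway.miss()
    origin = Point(x0 - plant_offset, z0)
    first = min(segments, key=lambda seg: origin.distance(Point(seg.coords[0])))
    coords = list(first.coords)
    entry_pt, exit_pt = coords[0], coords[-1]
    if origin.distance(Point(exit_pt)) < origin.distance(Point(entry_pt)):
        entry_pt, exit_pt = exit_pt, entry_pt
    entry_distance = origin.distance(Point(entry_pt))
    # report coordinates back in the flame frame (crown centred at offset)
    entry = (entry_pt[0] + plant_offset, entry_pt[1])
    exit_ = (exit_pt[0] + plant_offset, exit_pt[1])
    return PlumePathway(entry, exit_, float(entry_distance), float(total))
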