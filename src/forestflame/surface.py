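"""Pilot surface-fire sub-model.

A litter-bed flame provides the pilot that can ignite the near-surface
stratum; on its own it constitutes the surface-fuel-only treatment (F).
Flame length grows with fine fuel load, shrinks with dead fuel moisture and
stretches with near-ground wind. The relation is only trusted inside the
laboratory domain it was calibrated on, so inputs are clamped to the domain
box and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import ModelConfig
from .physics import flame_angle

import math

logger = logging.getLogger("forestflame")

__all__ = ["SurfaceFire", "surface_flame"]


@dataclass(frozen=True)
class SurfaceFire:
    flame_length: float   # m
    flame_angle: float    # radians from horizontal
    flame_height: float   # m; <= flame_length
    flame_duration: float  # s of flaming at a point
    in_domain: bool       # False when any input was clamped to the domain box


def _clamp(value: float, box) -> tuple[float, bool]:
    lo, hi = float(box[0]), float(box[1])
    clamped = min(max(value, lo), hi)
    return clamped, clamped == value


def surface_flame(
    fuel_load: float,
    dfmc: float,
    surface_wind: float,
    slope: float,
    config: ModelConfig,
) -> SurfaceFire:
    """Litter flame from fuel load (t/ha), DFMC (fraction ODW), near-ground
    wind (m/s, signed) and slope (degrees).

    Flame height is derived from the flame length via the shared
    flame-angle relation so the pilot is geometrically consistent with the
    rest of the simulator.
    """
    if fuel_load <= 0:
        raise ValueError("fuel_load must be > 0")
    c = config["surface_fire"]
    box = c["domain"]
    load_c, ok_load = _clamp(fuel_load, box["fuel_load_t_ha"])
    dfmc_c, ok_dfmc = _clamp(dfmc, box["dfmc"])
    wind_mag, ok_wind = _clamp(abs(surface_wind), box["wind_ms"])
    slope_c, ok_slope = _clamp(slope, box["slope_deg"])
    in_domain = ok_load and ok_dfmc and ok_wind and ok_slope
    if not in_domain:
        logger.warning("surface fire inputs clamped to calibration domain")

    length = (
        float(c["length_per_t_ha"])
        * load_c
        * math.exp(-float(c["dfmc_decay"]) * dfmc_c)
        * (1.0 + float(c["wind_coeff"]) * wind_mag)
    )
    signed_wind = math.copysign(wind_mag, surface_wind) if surface_wind else 0.0
    angle = flame_angle(length, signed_wind, slope_c, config)
    duration = float(c["duration_base_s"]) + float(c["duration_per_t_ha"]) * load_c
    return SurfaceFire(
        flame_length=length,
        flame_angle=angle,
        flame_height=length * math.sin(angle),
        flame_duration=duration,
        in_domain=in_domain,
    )
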