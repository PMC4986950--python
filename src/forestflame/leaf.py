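"""Leaf-scale flammability sub-models.

Four quantities summarise how a leaf takes part in fire:

* **ignitability** — the ignitability coefficient
  ``IC = moisture (%ODW) x thickness (mm) / number of leaf sides``; the
  larger the IC, the harder the leaf is to ignite;
* **time to ignition** — seconds of heating at a given plume temperature
  before a leaf with a given IC ignites; infinite below the leaf's minimum
  piloted ignition temperature (its endotherm);
* **sustainability** — flame duration, driven by the leaf cross-section
  (width x thickness) and moisture;
* **combustibility** — the flame length a single burning leaf produces,
  driven by leaf length, width and moisture.

Leaf moisture everywhere is the mean of live and dead moisture contents
weighted by the fraction of dead foliage in the plant; the dead component is
the site dead-fuel moisture content expressed in %ODW.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .config import ModelConfig
from .domain import LeafForm, SpeciesTraits, StratumStructure

logger = logging.getLogger("forestflame")

#: Sentinel for a plume too cool to ever ignite the receiver.
NO_IGNITION = math.inf

__all__ = [
    "NO_IGNITION",
    "LeafFlammability",
    "mean_leaf_moisture",
    "ignitability_coefficient",
    "time_to_ignition",
    "flame_duration",
    "leaf_flame_length",
    "leaf_flammability",
    "stratum_mean_flammability",
]


@dataclass(frozen=True)
class LeafFlammability:
    """Derived flammability summary for one species (or species mix)."""

    ic: float                    # %ODW.mm per heated side
    mean_moisture: float         # %ODW
    ignition_temperature: float  # degC
    flame_duration: float        # s
    leaf_flame_length: float     # m


def mean_leaf_moisture(live: float, dead: float, percent_dead: float) -> float:
    """Foliage moisture as the dead-fraction-weighted mean of live and dead
    moisture contents, all in %ODW."""
    if live <= 0 or dead <= 0:
        raise ValueError("moisture contents must be > 0")
    if not 0.0 <= percent_dead <= 1.0:
        raise ValueError("percent_dead must be in [0, 1]")
    return percent_dead * dead + (1.0 - percent_dead) * live


def ignitability_coefficient(
    moisture: float, thickness_mm: float, leaf_form: LeafForm, config: ModelConfig
) -> float:
    """IC = moisture (%ODW) x thickness (mm) / number of leaf sides."""
    if moisture <= 0 or thickness_mm <= 0:
        raise ValueError("moisture and thickness must be > 0")
    try:
        n_sides = config["n_sides"][leaf_form.value]
    except (KeyError, AttributeError) as exc:
        raise ValueError(f"unknown leaf form {leaf_form!r}") from exc
    return moisture * thickness_mm / n_sides


def time_to_ignition(
    plume_temp: float,
    ic: float,
    ignition_temperature: float,
    config: ModelConfig,
) -> float:
    """Seconds of heating required to ignite a leaf, or ``NO_IGNITION``.

    Below the endotherm no amount of heating ignites the leaf. At and above
    it, the required time decays exponentially with the temperature excess
    and grows linearly with IC, so hotter plumes ignite faster and
    thicker/moister leaves ignite slower.
    """
    c = config["time_to_ignition"]
    if c.get("formula", "exp_decay_ic") != "exp_decay_ic":
        raise ValueError(f"unknown time_to_ignition formula {c.get('formula')!r}")
    if plume_temp < ignition_temperature:
        return NO_IGNITION
    base = float(c["base_s"]) + float(c["ic_coeff_s"]) * max(ic, 0.0)
    return base * math.exp(-float(c["temp_decay_per_c"]) * (plume_temp - ignition_temperature))


def flame_duration(
    width: float, thickness: float, moisture: float, config: ModelConfig
) -> float:
    """Flame duration (s) of one leaf from its cross-section and moisture.

    ``width`` and ``thickness`` are metres; the fitted relation works on the
    cross-section area in mm^2.
    """
    c = config["flame_duration"]
    if c.get("formula", "linear_area_moisture") != "linear_area_moisture":
        raise ValueError(f"unknown flame_duration formula {c.get('formula')!r}")
    if width <= 0 or thickness <= 0:
        raise ValueError("leaf dimensions must be > 0")
    area_mm2 = (width * 1000.0) * (thickness * 1000.0)
    lo, hi = c.get("valid_area_mm2", (0.0, math.inf))
    if not lo <= area_mm2 <= hi:
        logger.warning("leaf cross-section %.2f mm^2 outside fitted range", area_mm2)
    dur = (
        float(c["base_s"])
        + float(c["area_coeff_s_per_mm2"]) * area_mm2
        + float(c["moisture_coeff_s_per_pct"]) * moisture
    )
    return max(dur, 0.0)


def leaf_flame_length(
    length: float, width: float, moisture: float, config: ModelConfig
) -> float:
    """Flame length (m) produced by one burning leaf.

    Grows with leaf length and (weakly) width, shrinks with moisture;
    clamped at zero so extrapolation never yields a negative flame.
    """
    c = config["leaf_flame_length"]
    if c.get("formula", "length_width_moisture") != "length_width_moisture":
        raise ValueError(f"unknown leaf_flame_length formula {c.get('formula')!r}")
    if length < 0 or width < 0:
        raise ValueError("leaf dimensions must be >= 0")
    lo, hi = c.get("valid_length_m", (0.0, math.inf))
    if not lo <= length <= hi:
        logger.warning("leaf length %.3f m outside fitted range", length)
    value = (
        float(c["length_coeff"])
        * length
        * (1.0 + float(c["width_coeff_per_mm"]) * width * 1000.0)
        * math.exp(-float(c["moisture_decay"]) * moisture / 100.0)
    )
    return max(value, 0.0)


def leaf_flammability(
    traits: SpeciesTraits, dfmc: float, config: ModelConfig
) -> LeafFlammability:
    """Assemble the flammability summary for one species.

    ``dfmc`` is the site dead fuel moisture as a fraction of oven-dry
    weight; it supplies the dead component of the mean leaf moisture
    (suspended dead foliage equilibrates with the litter).
    """
    moisture = mean_leaf_moisture(traits.live_moisture, dfmc * 100.0, traits.percent_dead)
    ic = ignitability_coefficient(moisture, traits.leaf_thickness_mm, traits.leaf_form, config)
    return LeafFlammability(
        ic=ic,
        mean_moisture=moisture,
        ignition_temperature=traits.ignition_temperature,
        flame_duration=flame_duration(
            traits.leaf_width, traits.leaf_thickness, moisture, config
        ),
        leaf_flame_length=leaf_flame_length(
            traits.leaf_length, traits.leaf_width, moisture, config
        ),
    )


def stratum_mean_flammability(
    stratum: StratumStructure, dfmc: float, config: ModelConfig
) -> LeafFlammability:
    """Composition-weighted mean flammability of a stratum's species mix."""
    parts = [leaf_flammability(sp, dfmc, config) for sp in stratum.species]
    return LeafFlammability(
        ic=stratum.weighted([p.ic for p in parts]),
        mean_moisture=stratum.weighted([p.mean_moisture for p in parts]),
        ignition_temperature=stratum.weighted([p.ignition_temperature for p in parts]),
        flame_duration=stratum.weighted([p.flame_duration for p in parts]),
        leaf_flame_length=stratum.weighted([p.leaf_flame_length for p in parts]),
    )
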