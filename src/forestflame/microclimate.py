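"""Leaf area index per stratum and the vertical wind profile.

Foliage above a flame shelters it from the wind. The amount of shelter is
governed by the leaf area index (LAI) of the overlying strata — one-sided
leaf area per unit ground area, assembled from leaf dimensions, leaves per
clump, clump packing within the crown, crown size and plant spacing. Wind
magnitude attenuates exponentially with the cumulative LAI overhead; the
wind reduction factor (WRF) is the ratio of above-canopy wind speed to the
speed at 1.5 m above ground.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ModelConfig
from .domain import SpeciesTraits, StratumStructure
from .physics import crown_polygon

__all__ = [
    "WindProfile",
    "species_lai",
    "stratum_lai",
    "clumps_per_crown",
    "leaves_per_plant",
    "wind_profile",
]


def clumps_per_crown(traits: SpeciesTraits, crown: StratumStructure) -> float:
    """Number of leaf clumps inside one plant crown.

    The crown volume (cross-section area x width) is occupied by clumps of
    diameter d spaced (d + separation) apart, i.e. a volumetric packing
    fraction of d^3 / (d + sep)^3.
    """
    d = traits.clump_diameter
    if d <= 0:
        return 0.0
    pitch = d + traits.clump_separation
    packing_fraction = (d / pitch) ** 3
    crown_volume = crown_polygon(crown).area * crown.crown_width
    clump_volume = math.pi / 6.0 * d ** 3
    return crown_volume * packing_fraction / clump_volume


def species_lai(traits: SpeciesTraits, crown: StratumStructure) -> float:
    """One-sided LAI contributed by one species filling the stratum:
    leaf area x leaves per clump x clumps per crown x crowns per ground area.

    The ground footprint of a plant is at least its crown width, so closely
    spaced wide crowns do not stack leaf area without bound.
    """
    leaf_area = traits.leaf_length * traits.leaf_width
    n_clumps = clumps_per_crown(traits, crown)
    footprint = max(crown.plant_separation, crown.crown_width)
    return leaf_area * traits.leaf_packing * n_clumps / footprint ** 2


def stratum_lai(stratum: StratumStructure) -> float:
    """Composition-weighted LAI of a stratum."""
    return stratum.weighted([species_lai(sp, stratum) for sp in stratum.species])


def leaves_per_plant(stratum: StratumStructure) -> int:
    """Total leaf count of one plant of the stratum's (weighted) species mix;
    the finite fuel pool the propagation engine can ignite."""
    count = stratum.weighted(
        [clumps_per_crown(sp, stratum) * sp.leaf_packing for sp in stratum.species]
    )
    return max(int(round(count)), 1)


@dataclass(frozen=True)
class WindProfile:
    """Vertical wind profile under layered foliage.

    ``layers`` holds (z_low, z_high, lai) for every sheltering stratum; the
    wind magnitude at height z is the open wind attenuated by the cumulative
    LAI strictly above z (a stratum part-way overhead contributes the
    overlapping fraction of its LAI). Sign of the open wind is preserved.
    """

    open_wind: float  # m/s, signed
    layers: tuple[tuple[float, float, float], ...]
    extinction_coeff: float
    reference_height: float = 1.5

    def lai_above(self, z: float) -> float:
        total = 0.0
        for z_lo, z_hi, lai in self.layers:
            if z_hi <= z_lo or lai <= 0:
                continue
            overlap = max(0.0, z_hi - max(z, z_lo))
            total += lai * overlap / (z_hi - z_lo)
        return total

    def speed_at(self, z: float) -> float:
        return self.open_wind * math.exp(-self.extinction_coeff * self.lai_above(z))

    @property
    def wrf(self) -> float:
        """Wind reduction factor: open wind / wind at the reference height.
        1.0 in the degenerate no-wind case."""
        if self.open_wind == 0:
            return 1.0
        return self.open_wind / self.speed_at(self.reference_height)

    def speeds(self, heights) -> dict[float, float]:
        return {float(z): self.speed_at(z) for z in heights}


def wind_profile(
    open_wind: float,
    strata: list[StratumStructure],
    config: ModelConfig,
) -> WindProfile:
    """Build the wind profile for the given sheltering strata.

    Pass only the strata that actually shelter (those not burning); with no
    strata the profile is the identity and WRF = 1.
    """
    c = config["wind_profile"]
    layers = tuple(
        (st.crown_base_centre_height, st.crown_height, stratum_lai(st))
        for st in strata
    )
    return WindProfile(
        open_wind=open_wind,
        layers=layers,
        extinction_coeff=float(c["extinction_coeff"]),
        reference_height=float(c["reference_height_m"]),
    )
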