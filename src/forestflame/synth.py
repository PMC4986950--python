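"""Seeded generator of synthetic sites, species tables, weather and
observed flame-height intervals.

The generator emulates montane dry/wet sclerophyll eucalypt forest: up to
four vegetation strata with crown geometry, plant spacing and surface fuel
loads drawn uniformly within field-realistic ranges (surface fuel
9.6-24.3 t/ha; winds -21 to 30 km/h; air temperature 12.5-37.6 degC;
relative humidity 13-63.5%; DFMC 3.6-13.7% ODW; slopes -28 to 21 degrees),
and 1-3 species per stratum sampled around synthetic trait archetypes
(eucalypt canopy, acacia midstorey, sclerophyll shrubs, grasses, ferns).

Observed flame-height intervals are manufactured by running the fully
specified simulation (FSL) on each generated site and widening the
prediction into an interval with a configurable relative half-width, so the
"truth" is recoverable by construction: with zero noise the FSL treatment
scores PCP = 1 and MAE = 0. Everything is deterministic given the seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .config import ModelConfig, load_config
from .domain import (
    LeafForm,
    ObservedFlameInterval,
    SiteStructure,
    SpeciesTraits,
    Stratum,
    StratumStructure,
    TaxonGroup,
    WeatherRecord,
    write_site_tables,
)
from .engine import run_site

__all__ = ["GeneratorConfig", "SyntheticStudy", "generate", "load_archetypes"]

# printed field ranges: (low, high) per stratum for structural parameters,
# bottom-up: near_surface, elevated, midstorey, canopy
STRUCTURE_RANGES = {
    "plant_separation": ((0.1, 3.6), (0.7, 8.9), (3.2, 26.4), (2.8, 14.1)),
    "crown_height": ((0.1, 1.0), (0.2, 6.0), (2.0, 15.0), (8.0, 35.0)),
    "crown_width": ((0.1, 1.9), (0.4, 4.2), (1.5, 10.2), (2.8, 6.8)),
}

WEATHER_RANGES = {
    "slope": (-28.0, 21.0),
    "wind_velocity": (-21.0, 30.0),
    "air_temperature": (12.5, 37.6),
    "relative_humidity": (13.0, 63.5),
    "dfmc": (0.036, 0.137),
}

SURFACE_FUEL_RANGE = (9.6, 24.3)

# probability each stratum is present in a generated site
PRESENCE = {
    Stratum.NEAR_SURFACE: 0.9,
    Stratum.ELEVATED: 0.75,
    Stratum.MIDSTOREY: 0.6,
    Stratum.CANOPY: 0.9,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling conditions for the synthetic study.

    ``interval_halfwidth`` is the relative half-width of the manufactured
    observed interval around the FSL prediction (0 gives noise-free
    intervals); ``cap_fraction`` of sites instead have their upper bound
    extended to the base of the next unconsumed stratum, mimicking the
    coarser field convention.
    """

    seed: int = 0
    n_sites: int = 20
    interval_halfwidth: float = 0.25
    cap_fraction: float = 0.2
    presence: Mapping[Stratum, float] = field(default_factory=lambda: dict(PRESENCE))

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.interval_halfwidth:
            raise ValueError("interval_halfwidth must be >= 0")


@dataclass(frozen=True)
class SyntheticStudy:
    sites: dict[str, SiteStructure]
    weather: dict[str, WeatherRecord]
    observed: list[ObservedFlameInterval]

    def bundles(self) -> dict[str, tuple[SiteStructure, WeatherRecord]]:
        return {sid: (self.sites[sid], self.weather[sid]) for sid in self.sites}

    def write(self, out_dir) -> None:
        """Write the CSV schema the domain reader consumes, plus observations."""
        import pandas as pd
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_site_tables(
            self.bundles(),
            out / "species.csv", out / "structure.csv", out / "weather.csv",
        )
        pd.DataFrame(
            [
                {"site_id": o.site_id, "lower_m": o.lower, "median_m": o.median, "upper_m": o.upper}
                for o in self.observed
            ]
        ).to_csv(out / "observations.csv", index=False)


def load_archetypes() -> dict[Stratum, list[dict]]:
    text = (
        importlib.resources.files("forestflame") / "data" / "archetypes.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {Stratum(k): v for k, v in raw.items()}


def _sample_species(
    rng: np.random.Generator, stratum: Stratum, archetype: dict, index: int
) -> SpeciesTraits:
    def draw(key):
        lo, hi = archetype[key]
        return float(rng.uniform(lo, hi))

    return SpeciesTraits(
        name=f"{archetype['name']}_{index}",
        stratum=stratum,
        leaf_form=LeafForm(archetype["leaf_form"]),
        leaf_thickness=draw("leaf_thickness_mm") / 1000.0,
        leaf_width=draw("leaf_width_m"),
        leaf_length=draw("leaf_length_m"),
        live_moisture=draw("live_moisture_pct"),
        percent_dead=draw("percent_dead"),
        ignition_temperature=draw("ignition_temp_c"),
        leaf_packing=float(np.round(draw("leaf_packing"))),
        clump_diameter=draw("clump_diameter_m"),
        clump_separation=draw("clump_separation_m"),
        taxon_group=TaxonGroup(archetype["taxon_group"]),
    ).validate()


def _sample_stratum(
    rng: np.random.Generator,
    stratum: Stratum,
    min_height: float,
    archetypes: list[dict],
) -> StratumStructure:
    order = stratum.order
    h_lo, h_hi = STRUCTURE_RANGES["crown_height"][order]
    h_lo = max(h_lo, min_height)
    crown_height = float(rng.uniform(h_lo, max(h_hi, h_lo + 1e-3)))
    # bases as proportions of crown height, edge base above centre base
    base_centre = float(rng.uniform(0.0, 0.6)) * crown_height
    base_edge = base_centre + float(rng.uniform(0.0, 0.15)) * crown_height
    top_edge = float(rng.uniform(0.7, 1.0)) * crown_height
    base_edge = min(base_edge, top_edge)
    sep_lo, sep_hi = STRUCTURE_RANGES["plant_separation"][order]
    w_lo, w_hi = STRUCTURE_RANGES["crown_width"][order]
    n_species = int(rng.integers(1, 4))
    picks = rng.choice(len(archetypes), size=n_species, replace=True)
    species = tuple(
        _sample_species(rng, stratum, archetypes[p], i) for i, p in enumerate(picks)
    )
    # clump diameter cannot exceed the crown's vertical extent
    depth = crown_height - base_centre
    import dataclasses

    species = tuple(
        sp
        if sp.clump_diameter <= depth
        else dataclasses.replace(sp, clump_diameter=max(depth * 0.8, 1e-3))
        for sp in species
    )
    return StratumStructure(
        stratum=stratum,
        species=species,
        plant_separation=float(rng.uniform(sep_lo, sep_hi)),
        crown_base_centre_height=base_centre,
        crown_base_edge_height=base_edge,
        crown_height=crown_height,
        crown_top_edge_height=top_edge,
        crown_width=float(rng.uniform(w_lo, w_hi)),
    ).validate()


def _sample_site(
    rng: np.random.Generator,
    sid: str,
    presence: Mapping[Stratum, float],
    archetypes: dict[Stratum, list[dict]],
) -> SiteStructure:
    strata: dict[Stratum, StratumStructure] = {}
    min_height = 0.0
    for stratum in sorted(Stratum, key=lambda s: s.order):
        if rng.uniform() < presence.get(stratum, 0.0):
            st = _sample_stratum(rng, stratum, min_height, archetypes[stratum])
            strata[stratum] = st
            min_height = st.crown_height
    return SiteStructure(
        site_id=sid,
        strata=strata,
        surface_fuel_load=float(rng.uniform(*SURFACE_FUEL_RANGE)),
    ).validate()


def _sample_weather(rng: np.random.Generator) -> WeatherRecord:
    return WeatherRecord(
        slope=float(rng.uniform(*WEATHER_RANGES["slope"])),
        wind_velocity=float(rng.uniform(*WEATHER_RANGES["wind_velocity"])),
        air_temperature=float(rng.uniform(*WEATHER_RANGES["air_temperature"])),
        relative_humidity=float(rng.uniform(*WEATHER_RANGES["relative_humidity"])),
        dfmc=float(rng.uniform(*WEATHER_RANGES["dfmc"])),
    ).validate()


def generate(
    config: GeneratorConfig,
    model_config: ModelConfig | None = None,
    observations: bool = True,
) -> SyntheticStudy:
    """Generate a synthetic study: sites, weather and observed intervals.

    Every generated structure passes domain validation. When
    ``observations`` is true each site is simulated under FSL and the
    predicted flame height becomes the interval median; set it false to
    skip the (relatively costly) simulations when only the structures are
    needed. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cfg = model_config or load_config()
    archetypes = load_archetypes()
    sites: dict[str, SiteStructure] = {}
    weather: dict[str, WeatherRecord] = {}
    observed: list[ObservedFlameInterval] = []
    for i in range(config.n_sites):
        sid = f"S{i + 1:03d}"
        sites[sid] = _sample_site(rng, sid, config.presence, archetypes)
        weather[sid] = _sample_weather(rng)
        capped = rng.uniform() < config.cap_fraction
        if observations:
            behaviour = run_site(sites[sid], weather[sid], cfg, record_trajectory=False)
            median = behaviour.max_flame_height
            h = config.interval_halfwidth
            lower = max(0.0, median * (1.0 - h))
            upper = median * (1.0 + h)
            if capped and h > 0:
                upper = max(upper, _next_unburnt_base(sites[sid], behaviour.strata_burnt, upper))
            observed.append(
                ObservedFlameInterval(sid, lower, median, upper).validate()
            )
    return SyntheticStudy(sites=sites, weather=weather, observed=observed)


def _next_unburnt_base(site: SiteStructure, burnt, upper: float) -> float:
    """Base height of the lowest unconsumed stratum above the flame."""
    for st in site.present():
        if st.stratum not in burnt and st.crown_base_centre_height >= upper:
            return st.crown_base_centre_height
    return upper
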