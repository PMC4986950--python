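"""Domain types, validation, default-trait rules and tabular I/O.

Every other module consumes the validated structures defined here.

Unit conventions
----------------
* lengths are metres, except leaf thickness which is *entered* in mm in the
  input tables (column name ``leaf_thickness_mm``) and stored in metres;
* temperatures are degrees Celsius;
* wind is carried in km/h as recorded in weather tables (signed relative to
  the direction of fire spread; flanking spread gets 0, opposing wind is
  negative) and converted to m/s at the :class:`WeatherRecord` boundary;
* moisture contents are percent of oven-dry weight (%ODW) for foliage and a
  fraction of oven-dry weight for dead fine fuel (DFMC);
* ``percent_dead`` is stored as a fraction in [0, 1];
* heights are metres above ground; crown geometry is stored as absolute
  heights.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import ModelConfig, load_config

__all__ = [
    "Stratum",
    "LeafForm",
    "TaxonGroup",
    "SpeciesTraits",
    "StratumStructure",
    "SiteStructure",
    "WeatherRecord",
    "ObservedFlameInterval",
    "ValidationError",
    "apply_default_traits",
    "read_site_tables",
    "write_site_tables",
    "site_bundle_to_json",
]

KMH_TO_MS = 1000.0 / 3600.0

#: Upper bound of ambient air temperature the model accepts (deg C); leaf
#: ignition temperatures must sit above it.
MAX_AMBIENT_C = 37.6


class ValidationError(ValueError):
    """An input structure violates a domain invariant."""


class Stratum(enum.Enum):
    """Vegetation layer, ordered from the ground up."""

    NEAR_SURFACE = "near_surface"
    ELEVATED = "elevated"
    MIDSTOREY = "midstorey"
    CANOPY = "canopy"

    @property
    def order(self) -> int:
        return _STRATUM_ORDER[self]


_STRATUM_ORDER = {
    Stratum.NEAR_SURFACE: 0,
    Stratum.ELEVATED: 1,
    Stratum.MIDSTOREY: 2,
    Stratum.CANOPY: 3,
}

STRATA_BOTTOM_UP = tuple(sorted(Stratum, key=lambda s: s.order))


class LeafForm(enum.Enum):
    FLAT = "flat"
    ROUND = "round"


class TaxonGroup(enum.Enum):
    MONOCOT = "monocotyledon"
    DICOT = "dicotyledon"


@dataclass(frozen=True)
class SpeciesTraits:
    """Leaf morphology, moisture, chemistry and clump geometry for one
    species in one stratum.

    ``leaf_thickness`` is stored in metres even though tabular input uses mm.
    ``live_moisture`` is %ODW; ``percent_dead`` is the fraction of dead
    foliage in the plant, used to weight live and dead moisture into the
    mean leaf moisture.
    """

    name: str
    stratum: Stratum
    leaf_form: LeafForm
    leaf_thickness: float
    leaf_width: float
    leaf_length: float
    live_moisture: float
    percent_dead: float
    ignition_temperature: float
    leaf_packing: float
    clump_diameter: float
    clump_separation: float
    taxon_group: TaxonGroup

    def validate(self) -> "SpeciesTraits":
        for fname in ("leaf_thickness", "leaf_width", "leaf_length", "clump_diameter"):
            if not getattr(self, fname) > 0:
                raise ValidationError(f"{self.name}: {fname} must be > 0")
        if self.clump_separation < 0:
            raise ValidationError(f"{self.name}: clump_separation must be >= 0")
        if not 0.0 <= self.percent_dead <= 1.0:
            raise ValidationError(f"{self.name}: percent_dead must be in [0, 1]")
        if not self.live_moisture > 0:
            raise ValidationError(f"{self.name}: live_moisture must be > 0")
        if not self.ignition_temperature > MAX_AMBIENT_C:
            raise ValidationError(
                f"{self.name}: ignition_temperature must exceed the ambient "
                f"upper bound of {MAX_AMBIENT_C} degC"
            )
        if self.leaf_form is LeafForm.FLAT and self.leaf_width < self.leaf_thickness:
            raise ValidationError(
                f"{self.name}: flat leaves require leaf_width >= leaf_thickness"
            )
        if not self.leaf_packing >= 0:
            raise ValidationError(f"{self.name}: leaf_packing must be >= 0")
        return self

    @property
    def leaf_thickness_mm(self) -> float:
        return self.leaf_thickness * 1000.0


@dataclass(frozen=True)
class StratumStructure:
    """Per-stratum plant geometry and species composition.

    Crown geometry is the symmetric cross-section implied by five heights and
    a width: the crown base sits at ``crown_base_centre_height`` on the
    centreline rising to ``crown_base_edge_height`` at the edges, the top at
    ``crown_height`` on the centreline dropping to ``crown_top_edge_height``
    at the edges.
    """

    stratum: Stratum
    species: tuple[SpeciesTraits, ...]
    plant_separation: float
    crown_base_centre_height: float
    crown_base_edge_height: float
    crown_height: float
    crown_top_edge_height: float
    crown_width: float
    composition: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.composition:
            n = len(self.species)
            object.__setattr__(self, "composition", tuple([1.0 / n] * n) if n else ())
        object.__setattr__(self, "species", tuple(self.species))

    def validate(self) -> "StratumStructure":
        s = self.stratum.value
        if not self.species:
            raise ValidationError(f"{s}: stratum must contain at least one species")
        if len(self.composition) != len(self.species):
            raise ValidationError(f"{s}: composition length mismatch")
        if abs(sum(self.composition) - 1.0) > 1e-6:
            raise ValidationError(f"{s}: composition weights must sum to 1")
        if any(w < 0 for w in self.composition):
            raise ValidationError(f"{s}: composition weights must be >= 0")
        if not 0.0 <= self.crown_base_centre_height <= self.crown_base_edge_height:
            raise ValidationError(
                f"{s}: require 0 <= crown_base_centre <= crown_base_edge"
            )
        if self.crown_base_edge_height > self.crown_height:
            raise ValidationError(f"{s}: crown_base_edge above crown_height")
        if self.crown_top_edge_height > self.crown_height:
            raise ValidationError(f"{s}: crown_top_edge above crown_height")
        if self.crown_base_edge_height > self.crown_top_edge_height:
            raise ValidationError(f"{s}: crown_base_edge above crown_top_edge")
        if not self.crown_base_centre_height < self.crown_height:
            raise ValidationError(f"{s}: crown must have positive vertical extent")
        if not self.plant_separation > 0:
            raise ValidationError(f"{s}: plant_separation must be > 0")
        if not self.crown_width > 0:
            raise ValidationError(f"{s}: crown_width must be > 0")
        for sp in self.species:
            sp.validate()
            if sp.stratum is not self.stratum:
                raise ValidationError(
                    f"{s}: species {sp.name} tagged for stratum {sp.stratum.value}"
                )
        return self

    @property
    def crown_depth(self) -> float:
        return self.crown_height - self.crown_base_centre_height

    def weighted(self, values: Sequence[float]) -> float:
        """Composition-weighted mean of one value per species."""
        return float(sum(w * v for w, v in zip(self.composition, values)))


@dataclass(frozen=True)
class SiteStructure:
    """One site: up to four strata (any may be absent) plus surface fuel."""

    site_id: str
    strata: Mapping[Stratum, StratumStructure]
    surface_fuel_load: float  # t/ha of fine surface litter

    def validate(self) -> "SiteStructure":
        if not self.surface_fuel_load > 0:
            raise ValidationError(f"{self.site_id}: surface_fuel_load must be > 0")
        prev_top = -math.inf
        for stratum in STRATA_BOTTOM_UP:
            st = self.strata.get(stratum)
            if st is None:
                continue
            st.validate()
            if st.stratum is not stratum:
                raise ValidationError(f"{self.site_id}: stratum key/label mismatch")
            if st.crown_height < prev_top:
                raise ValidationError(
                    f"{self.site_id}: strata crown heights must be ordered "
                    "near_surface <= elevated <= midstorey <= canopy"
                )
            prev_top = st.crown_height
        return self

    def present(self) -> tuple[StratumStructure, ...]:
        """Strata present at the site, bottom-up."""
        return tuple(
            self.strata[s] for s in STRATA_BOTTOM_UP if s in self.strata
        )


@dataclass(frozen=True)
class WeatherRecord:
    """Exogenous drivers for one site burn.

    ``wind_velocity`` is km/h, signed relative to the direction of spread;
    ``slope`` is degrees, negative for downslope spread; ``dfmc`` is dead
    fuel moisture as a fraction of oven-dry weight.
    """

    slope: float
    wind_velocity: float
    air_temperature: float
    relative_humidity: float
    dfmc: float

    def validate(self) -> "WeatherRecord":
        if not self.dfmc > 0:
            raise ValidationError("dfmc must be > 0")
        if not 0 < self.relative_humidity <= 100:
            raise ValidationError("relative_humidity must be in (0, 100]")
        if abs(self.slope) > 45:
            raise ValidationError("|slope| must be <= 45 degrees")
        return self

    @property
    def wind_speed_ms(self) -> float:
        """Signed open wind speed in m/s."""
        return self.wind_velocity * KMH_TO_MS


@dataclass(frozen=True)
class ObservedFlameInterval:
    """Field flame-height interval for one site.

    The lower bound is the height of combustion; the upper is the lowest of
    the scorch height or the base of the next unconsumed stratum.
    """

    site_id: str
    lower: float
    median: float
    upper: float

    def validate(self) -> "ObservedFlameInterval":
        if not 0 <= self.lower <= self.median <= self.upper:
            raise ValidationError(
                f"{self.site_id}: require 0 <= lower <= median <= upper"
            )
        return self


# ---------------------------------------------------------------------------
# Default trait rules
# ---------------------------------------------------------------------------

_MANDATORY = ("name", "stratum", "leaf_form", "leaf_thickness", "leaf_width", "leaf_length")


def apply_default_traits(
    raw: Mapping[str, object], config: ModelConfig | None = None
) -> SpeciesTraits:
    """Fill missing trait values of a partial species record by rule.

    ``raw`` must supply at least name, stratum, leaf form and the three leaf
    dimensions (metres). Missing values are filled from the configured rules:

    * ``live_moisture`` by functional group — 100 %ODW standard, 150 for
      herbs and some mesic species, 200 for very green herbs and mesic
      species (``raw['functional_group']`` in standard/mesic/very_green);
    * ``ignition_temperature`` by aromaticity (220 vs 260 degC via
      ``raw['aromatic']``), or for grasses and ferns supplying
      ``silica_free_ash_pct``, by the configured linear ash relation;
    * ``percent_dead`` — 0.5 for C4 grasses (``raw['c4_grass']``), else 0.

    Complete records pass through unchanged.
    """
    cfg = (config or load_config()).raw["default_traits"]
    missing = [k for k in _MANDATORY if raw.get(k) is None]
    if missing:
        raise ValidationError(f"missing mandatory morphological field(s): {missing}")

    def get(key, default=None):
        v = raw.get(key)
        return default if v is None else v

    live_moisture = raw.get("live_moisture")
    if live_moisture is None:
        group = str(get("functional_group", "standard"))
        try:
            live_moisture = cfg["moisture_odw"][group]
        except KeyError as exc:
            raise ValidationError(f"unknown functional_group {group!r}") from exc

    ignition = raw.get("ignition_temperature")
    if ignition is None:
        ash = raw.get("silica_free_ash_pct")
        if ash is not None:
            rel = cfg["ash_relation"]
            ignition = rel["intercept_c"] + rel["slope_c_per_pct"] * float(ash)
        else:
            key = "aromatic" if get("aromatic", False) else "non_aromatic"
            ignition = cfg["endotherm_c"][key]

    percent_dead = raw.get("percent_dead")
    if percent_dead is None:
        percent_dead = (
            cfg["percent_dead"]["c4_grass"]
            if get("c4_grass", False)
            else cfg["percent_dead"]["default"]
        )

    stratum = raw["stratum"]
    leaf_form = raw["leaf_form"]
    taxon = get("taxon_group", TaxonGroup.DICOT)
    return SpeciesTraits(
        name=str(raw["name"]),
        stratum=stratum if isinstance(stratum, Stratum) else Stratum(str(stratum)),
        leaf_form=leaf_form if isinstance(leaf_form, LeafForm) else LeafForm(str(leaf_form)),
        leaf_thickness=float(raw["leaf_thickness"]),
        leaf_width=float(raw["leaf_width"]),
        leaf_length=float(raw["leaf_length"]),
        live_moisture=float(live_moisture),
        percent_dead=float(percent_dead),
        ignition_temperature=float(ignition),
        leaf_packing=float(get("leaf_packing", 0.0)),
        clump_diameter=float(get("clump_diameter", 0.0)),
        clump_separation=float(get("clump_separation", 0.0)),
        taxon_group=taxon if isinstance(taxon, TaxonGroup) else TaxonGroup(str(taxon)),
    ).validate()


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SPECIES_COLUMNS = [
    "site_id", "stratum", "name", "composition", "leaf_form",
    "leaf_thickness_mm", "leaf_width_m", "leaf_length_m", "live_moisture_pct",
    "percent_dead_frac", "ignition_temp_c", "leaf_packing",
    "clump_diameter_m", "clump_separation_m", "taxon_group",
]

STRUCTURE_COLUMNS = [
    "site_id", "stratum", "plant_separation_m", "crown_base_centre_m",
    "crown_base_edge_m", "crown_height_m", "crown_top_edge_m",
    "crown_width_m", "surface_fuel_t_ha",
]

WEATHER_COLUMNS = [
    "site_id", "slope_deg", "wind_kmh", "air_temp_c", "rh_pct", "dfmc_frac",
]


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _species_from_row(row: pd.Series, line: int, path) -> tuple[SpeciesTraits, float]:
    try:
        traits = SpeciesTraits(
            name=str(row["name"]),
            stratum=Stratum(str(row["stratum"])),
            leaf_form=LeafForm(str(row["leaf_form"])),
            leaf_thickness=float(row["leaf_thickness_mm"]) / 1000.0,
            leaf_width=float(row["leaf_width_m"]),
            leaf_length=float(row["leaf_length_m"]),
            live_moisture=float(row["live_moisture_pct"]),
            percent_dead=float(row["percent_dead_frac"]),
            ignition_temperature=float(row["ignition_temp_c"]),
            leaf_packing=float(row["leaf_packing"]),
            clump_diameter=float(row["clump_diameter_m"]),
            clump_separation=float(row["clump_separation_m"]),
            taxon_group=TaxonGroup(str(row["taxon_group"])),
        ).validate()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}, line {line}: {exc}") from exc
    comp = row.get("composition")
    weight = float(comp) if comp is not None and not pd.isna(comp) else math.nan
    return traits, weight


def read_site_tables(
    species_path, structure_path, weather_path
) -> dict[str, tuple[SiteStructure, WeatherRecord]]:
    """Read the CSV triplet describing sites and return validated bundles.

    Returns a mapping ``site_id -> (SiteStructure, WeatherRecord)``. Rows
    that violate an invariant are reported with their file and line number.
    Species composition weights within a stratum are normalised to sum to 1;
    when the column is blank, equal weights are used.
    """
    species_df = pd.read_csv(species_path)
    structure_df = pd.read_csv(structure_path)
    weather_df = pd.read_csv(weather_path)
    _check_columns(species_df, [c for c in SPECIES_COLUMNS if c != "composition"], species_path)
    _check_columns(structure_df, STRUCTURE_COLUMNS, structure_path)
    _check_columns(weather_df, WEATHER_COLUMNS, weather_path)

    species_by_key: dict[tuple[str, Stratum], list[tuple[SpeciesTraits, float]]] = {}
    for i, row in species_df.iterrows():
        traits, weight = _species_from_row(row, i + 2, species_path)
        species_by_key.setdefault((str(row["site_id"]), traits.stratum), []).append(
            (traits, weight)
        )

    sites: dict[str, tuple[SiteStructure, WeatherRecord]] = {}
    strata_by_site: dict[str, dict[Stratum, StratumStructure]] = {}
    fuel_by_site: dict[str, float] = {}
    for i, row in structure_df.iterrows():
        line = i + 2
        sid = str(row["site_id"])
        try:
            stratum = Stratum(str(row["stratum"]))
            entries = species_by_key.get((sid, stratum))
            if not entries:
                raise ValidationError(f"no species listed for stratum {stratum.value}")
            weights = [w for _, w in entries]
            if all(math.isnan(w) for w in weights):
                weights = [1.0 / len(entries)] * len(entries)
            elif any(math.isnan(w) for w in weights):
                raise ValidationError("composition weights partially specified")
            else:
                total = sum(weights)
                if total <= 0:
                    raise ValidationError("composition weights must sum > 0")
                weights = [w / total for w in weights]
            st = StratumStructure(
                stratum=stratum,
                species=tuple(t for t, _ in entries),
                plant_separation=float(row["plant_separation_m"]),
                crown_base_centre_height=float(row["crown_base_centre_m"]),
                crown_base_edge_height=float(row["crown_base_edge_m"]),
                crown_height=float(row["crown_height_m"]),
                crown_top_edge_height=float(row["crown_top_edge_m"]),
                crown_width=float(row["crown_width_m"]),
                composition=tuple(weights),
            ).validate()
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{structure_path}, line {line}: {exc}") from exc
        site_strata = strata_by_site.setdefault(sid, {})
        if stratum in site_strata:
            raise ValidationError(
                f"{structure_path}, line {line}: duplicate stratum {stratum.value}"
            )
        site_strata[stratum] = st
        fuel_by_site[sid] = float(row["surface_fuel_t_ha"])

    weather_by_site: dict[str, WeatherRecord] = {}
    for i, row in weather_df.iterrows():
        line = i + 2
        sid = str(row["site_id"])
        try:
            weather_by_site[sid] = WeatherRecord(
                slope=float(row["slope_deg"]),
                wind_velocity=float(row["wind_kmh"]),
                air_temperature=float(row["air_temp_c"]),
                relative_humidity=float(row["rh_pct"]),
                dfmc=float(row["dfmc_frac"]),
            ).validate()
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{weather_path}, line {line}: {exc}") from exc

    for sid in weather_by_site:
        if sid not in fuel_by_site:
            # surface-fuel-only site: allowed, but the structure table must
            # still carry its fuel load via a row; absent sites are skipped
            continue
        site = SiteStructure(
            site_id=sid,
            strata=strata_by_site.get(sid, {}),
            surface_fuel_load=fuel_by_site[sid],
        ).validate()
        sites[sid] = (site, weather_by_site[sid])
    return sites


def write_site_tables(
    bundles: Mapping[str, tuple[SiteStructure, WeatherRecord]],
    species_path, structure_path, weather_path,
) -> None:
    """Inverse of :func:`read_site_tables` (lossless to float precision)."""
    sp_rows, st_rows, wx_rows = [], [], []
    for sid in sorted(bundles):
        site, weather = bundles[sid]
        for st in site.present():
            for traits, w in zip(st.species, st.composition):
                sp_rows.append({
                    "site_id": sid,
                    "stratum": st.stratum.value,
                    "name": traits.name,
                    "composition": w,
                    "leaf_form": traits.leaf_form.value,
                    "leaf_thickness_mm": traits.leaf_thickness_mm,
                    "leaf_width_m": traits.leaf_width,
                    "leaf_length_m": traits.leaf_length,
                    "live_moisture_pct": traits.live_moisture,
                    "percent_dead_frac": traits.percent_dead,
                    "ignition_temp_c": traits.ignition_temperature,
                    "leaf_packing": traits.leaf_packing,
                    "clump_diameter_m": traits.clump_diameter,
                    "clump_separation_m": traits.clump_separation,
                    "taxon_group": traits.taxon_group.value,
                })
            st_rows.append({
                "site_id": sid,
                "stratum": st.stratum.value,
                "plant_separation_m": st.plant_separation,
                "crown_base_centre_m": st.crown_base_centre_height,
                "crown_base_edge_m": st.crown_base_edge_height,
                "crown_height_m": st.crown_height,
                "crown_top_edge_m": st.crown_top_edge_height,
                "crown_width_m": st.crown_width,
                "surface_fuel_t_ha": site.surface_fuel_load,
            })
        wx_rows.append({
            "site_id": sid,
            "slope_deg": weather.slope,
            "wind_kmh": weather.wind_velocity,
            "air_temp_c": weather.air_temperature,
            "rh_pct": weather.relative_humidity,
            "dfmc_frac": weather.dfmc,
        })
    pd.DataFrame(sp_rows, columns=SPECIES_COLUMNS).to_csv(species_path, index=False)
    pd.DataFrame(st_rows, columns=STRUCTURE_COLUMNS).to_csv(structure_path, index=False)
    pd.DataFrame(wx_rows, columns=WEATHER_COLUMNS).to_csv(weather_path, index=False)


def site_bundle_to_json(site: SiteStructure, weather: WeatherRecord) -> str:
    """JSON export of one validated site bundle."""

    def species_dict(traits: SpeciesTraits) -> dict:
        d = dataclasses.asdict(traits)
        for k, v in d.items():
            if isinstance(v, enum.Enum):
                d[k] = v.value
        return d

    payload = {
        "site": {
            "site_id": site.site_id,
            "surface_fuel_load_t_ha": site.surface_fuel_load,
            "strata": {
                st.stratum.value: {
                    "plant_separation_m": st.plant_separation,
                    "crown_base_centre_m": st.crown_base_centre_height,
                    "crown_base_edge_m": st.crown_base_edge_height,
                    "crown_height_m": st.crown_height,
                    "crown_top_edge_m": st.crown_top_edge_height,
                    "crown_width_m": st.crown_width,
                    "composition": list(st.composition),
                    "species": [species_dict(sp) for sp in st.species],
                }
                for st in site.present()
            },
        },
        "weather": dataclasses.asdict(weather),
    }
    return json.dumps(payload, indent=2)
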