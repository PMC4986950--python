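"""The three comparative treatments.

* **F** — surface fuel only: the litter flame under the overstorey-sheltered
  wind, with no standing-plant ignition attempted.
* **FS** — surface fuel plus stand structure: the full engine, but leaf
  traits replaced by monocotyledon/dicotyledon group means and internal
  clump structure collapsed to one uniform clump filling the crown.
* **FSL** — surface fuel, structure and leaf traits: the full engine with
  species-specific traits and clump structure.

Each treatment emits a :class:`PredictionRecord` carrying the predicted
flame height plus the covariates the sensitivity analysis consumes (donor
flame heights, LAI sums, mean IC, WRF).
"""

from __future__ import annotations

import dataclasses
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .config import ModelConfig
from .domain import (
    SiteStructure,
    SpeciesTraits,
    Stratum,
    StratumStructure,
    TaxonGroup,
    WeatherRecord,
)
from .engine import run_site
from .leaf import leaf_flammability
from .microclimate import stratum_lai, wind_profile
from .surface import surface_flame

__all__ = [
    "PredictionRecord",
    "compute_group_means",
    "fs_transform",
    "run_treatment_F",
    "run_treatment_FS",
    "run_treatment_FSL",
    "run_all_treatments",
    "predictions_frame",
]

TREATMENTS = ("F", "FS", "FSL")


@dataclass(frozen=True)
class PredictionRecord:
    site_id: str
    treatment: str
    predicted_flame_height: float
    donor_flame_heights: Mapping[str, float]
    sum_lai: float
    canopy_lai: float
    mean_ic: float
    wrf: float


_MEAN_FIELDS = (
    "leaf_thickness", "leaf_width", "leaf_length", "live_moisture",
    "percent_dead", "ignition_temperature", "leaf_packing",
    "clump_diameter", "clump_separation",
)

def compute_group_means(
    species: Iterable[SpeciesTraits],
) -> dict[TaxonGroup, dict[str, object]]:
    """Unweighted trait means per taxon group over a species table.

    Numeric fields — including the clump parameters, which FS replaces with
    the group norm — are averaged; leaf form is the group's modal form.
    """
    by_group: dict[TaxonGroup, list[SpeciesTraits]] = {}
    for sp in species:
        by_group.setdefault(sp.taxon_group, []).append(sp)
    means: dict[TaxonGroup, dict[str, object]] = {}
    for group, members in by_group.items():
        entry: dict[str, object] = {
            f: statistics.fmean(getattr(sp, f) for sp in members) for f in _MEAN_FIELDS
        }
        forms = [sp.leaf_form for sp in members]
        entry["leaf_form"] = max(set(forms), key=forms.count)
        means[group] = entry
    return means


def fs_transform(
    site: SiteStructure, group_means: Mapping[TaxonGroup, Mapping[str, object]]
) -> SiteStructure:
    """Rewrite a site for treatment FS.

    Every species' leaf traits become its taxon-group mean, and the
    species-specific internal layout is no longer characterised: clump
    diameter, separation and leaf packing are likewise replaced by the
    group norm (diameter capped at the crown depth so the clump still fits
    the crown envelope, the only structure FS retains).
    """
    new_strata: dict[Stratum, StratumStructure] = {}
    for st in site.present():
        depth = max(st.crown_depth, 1e-3)
        new_species = []
        for sp in st.species:
            try:
                gm = group_means[sp.taxon_group]
            except KeyError as exc:
                raise ValueError(
                    f"no group mean for taxon group {sp.taxon_group.value}"
                ) from exc
            new_species.append(
                dataclasses.replace(
                    sp,
                    name=f"{sp.taxon_group.value}_mean",
                    leaf_form=gm["leaf_form"],
                    leaf_thickness=float(gm["leaf_thickness"]),
                    leaf_width=float(gm["leaf_width"]),
                    leaf_length=float(gm["leaf_length"]),
                    live_moisture=float(gm["live_moisture"]),
                    percent_dead=float(gm["percent_dead"]),
                    ignition_temperature=float(gm["ignition_temperature"]),
                    leaf_packing=float(gm["leaf_packing"]),
                    clump_diameter=min(float(gm["clump_diameter"]), depth),
                    clump_separation=float(gm["clump_separation"]),
                ).validate()
            )
        new_strata[st.stratum] = dataclasses.replace(
            st, species=tuple(new_species)
        ).validate()
    return dataclasses.replace(site, strata=new_strata).validate()


def _site_covariates(
    site: SiteStructure, weather: WeatherRecord, config: ModelConfig
) -> tuple[float, float, float, float]:
    """(sum_lai, canopy_lai, mean_ic, wrf) for the intact (pre-fire) stand."""
    present = site.present()
    lais = {st.stratum: stratum_lai(st) for st in present}
    sum_lai = float(sum(lais.values()))
    canopy_lai = float(lais.get(Stratum.CANOPY, 0.0))
    ics = [
        leaf_flammability(sp, weather.dfmc, config).ic
        for st in present
        for sp in st.species
    ]
    mean_ic = float(statistics.fmean(ics)) if ics else 0.0
    profile = wind_profile(weather.wind_speed_ms, list(present), config)
    return sum_lai, canopy_lai, mean_ic, float(profile.wrf)


def run_treatment_F(
    site: SiteStructure, weather: WeatherRecord, config: ModelConfig
) -> PredictionRecord:
    """Surface-fuel-only prediction.

    The only influence standing vegetation retains is wind sheltering via
    its LAI; no stratum ignition is attempted.
    """
    site.validate()
    weather.validate()
    sum_lai, canopy_lai, mean_ic, wrf = _site_covariates(site, weather, config)
    ref_height = float(config["wind_profile"]["reference_height_m"])
    profile = wind_profile(weather.wind_speed_ms, list(site.present()), config)
    surf = surface_flame(
        site.surface_fuel_load, weather.dfmc, profile.speed_at(ref_height),
        weather.slope, config,
    )
    return PredictionRecord(
        site_id=site.site_id,
        treatment="F",
        predicted_flame_height=surf.flame_height,
        donor_flame_heights={"surface": surf.flame_height},
        sum_lai=sum_lai,
        canopy_lai=canopy_lai,
        mean_ic=mean_ic,
        wrf=wrf,
    )


def _engine_record(
    site: SiteStructure, weather: WeatherRecord, config: ModelConfig, treatment: str
) -> PredictionRecord:
    sum_lai, canopy_lai, mean_ic, wrf = _site_covariates(site, weather, config)
    behaviour = run_site(site, weather, config, record_trajectory=False)
    return PredictionRecord(
        site_id=site.site_id,
        treatment=treatment,
        predicted_flame_height=behaviour.max_flame_height,
        donor_flame_heights=dict(behaviour.donor_flame_heights),
        sum_lai=sum_lai,
        canopy_lai=canopy_lai,
        mean_ic=mean_ic,
        wrf=wrf,
    )


def run_treatment_FS(
    site: SiteStructure,
    weather: WeatherRecord,
    config: ModelConfig,
    group_means: Mapping[TaxonGroup, Mapping[str, object]],
) -> PredictionRecord:
    """Structure-only prediction: group-mean traits, crown-envelope clumps."""
    return _engine_record(fs_transform(site, group_means), weather, config, "FS")


def run_treatment_FSL(
    site: SiteStructure, weather: WeatherRecord, config: ModelConfig
) -> PredictionRecord:
    """Fully specified prediction with species traits and clump structure."""
    return _engine_record(site, weather, config, "FSL")


def run_all_treatments(
    bundles: Mapping[str, tuple[SiteStructure, WeatherRecord]],
    config: ModelConfig,
    group_means: Mapping[TaxonGroup, Mapping[str, object]] | None = None,
) -> list[PredictionRecord]:
    """All three treatments per site; group means default to the means over
    every species of every supplied site."""
    if group_means is None:
        group_means = compute_group_means(
            sp
            for site, _ in bundles.values()
            for st in site.present()
            for sp in st.species
        )
    records = []
    for sid in sorted(bundles):
        site, weather = bundles[sid]
        records.append(run_treatment_F(site, weather, config))
        records.append(run_treatment_FS(site, weather, config, group_means))
        records.append(run_treatment_FSL(site, weather, config))
    return records


def predictions_frame(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    """Tidy frame (one row per site x treatment) for validation/sensitivity."""
    rows = []
    for r in records:
        donor = {f"donor_fh_{k}": v for k, v in r.donor_flame_heights.items()}
        rows.append(
            {
                "site_id": r.site_id,
                "treatment": r.treatment,
                "predicted_m": r.predicted_flame_height,
                "sum_lai": r.sum_lai,
                "canopy_lai": r.canopy_lai,
                "mean_ic": r.mean_ic,
                "wrf": r.wrf,
                **donor,
            }
        )
    df = pd.DataFrame(rows)
    donor_cols = [c for c in df.columns if c.startswith("donor_fh_")]
    df[donor_cols] = df[donor_cols].fillna(0.0)
    return df
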