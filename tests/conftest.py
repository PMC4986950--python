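import pytest

import forestflame as ff


@pytest.fixture(scope="session")
def cfg():
    return ff.load_config()


def make_traits(**overrides) -> ff.SpeciesTraits:
    """Eucalypt-like flat leaf in the near-surface stratum by default."""
    base = dict(
        name="test_shrub",
        stratum=ff.Stratum.NEAR_SURFACE,
        leaf_form=ff.LeafForm.FLAT,
        leaf_thickness=0.0004,
        leaf_width=0.01,
        leaf_length=0.05,
        live_moisture=100.0,
        percent_dead=0.1,
        ignition_temperature=260.0,
        leaf_packing=60.0,
        clump_diameter=0.25,
        clump_separation=0.05,
        taxon_group=ff.TaxonGroup.DICOT,
    )
    base.update(overrides)
    return ff.SpeciesTraits(**base).validate()


def make_stratum(traits=None, **overrides) -> ff.StratumStructure:
    species = (traits or make_traits(),)
    base = dict(
        stratum=species[0].stratum,
        species=species,
        plant_separation=0.7,
        crown_base_centre_height=0.0,
        crown_base_edge_height=0.05,
        crown_height=0.6,
        crown_top_edge_height=0.5,
        crown_width=0.8,
    )
    base.update(overrides)
    return ff.StratumStructure(**base).validate()


def make_site(strata=None, site_id="T1", surface_fuel_load=15.0) -> ff.SiteStructure:
    if strata is None:
        strata = [make_stratum()]
    return ff.SiteStructure(
        site_id=site_id,
        strata={st.stratum: st for st in strata},
        surface_fuel_load=surface_fuel_load,
    ).validate()


def make_weather(**overrides) -> ff.WeatherRecord:
    base = dict(
        slope=0.0,
        wind_velocity=10.0,
        air_temperature=30.0,
        relative_humidity=30.0,
        dfmc=0.07,
    )
    base.update(overrides)
    return ff.WeatherRecord(**base).validate()


@pytest.fixture
def ns_site():
    return make_site()


@pytest.fixture
def weather():
    return make_weather()


@pytest.fixture(scope="session")
def small_study(cfg):
    """Six synthetic sites with noisy observed intervals."""
    return ff.generate(ff.GeneratorConfig(seed=7, n_sites=6), model_config=cfg)


@pytest.fixture(scope="session")
def noise_free_study(cfg):
    """Eight synthetic sites whose observed intervals equal the simulated truth."""
    return ff.generate(
        ff.GeneratorConfig(seed=11, n_sites=8, interval_halfwidth=0.0, cap_fraction=0.0),
        model_config=cfg,
    )
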