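"""Propagation engine: ignition depth, leaf counting, cohort bookkeeping
and whole-site runs, each checked against independent oracles."""

import math

import pytest

import forestflame as ff
from forestflame.engine import ClumpGeometry, _ignition_length
from forestflame.leaf import stratum_mean_flammability
from forestflame.microclimate import leaves_per_plant

from conftest import make_site, make_stratum, make_traits, make_weather


def flame(origin=0.0, length=1.0, angle=math.pi / 2, temp=950.0, dur=10.0):
    return ff.FlameSegment(origin, length, angle, temp, dur)


RECEIVER = ff.LeafFlammability(
    ic=18.0, mean_moisture=95.0, ignition_temperature=260.0,
    flame_duration=3.0, leaf_flame_length=0.1,
)


def scan_depth(donor, receiver, ambient, cfg, step=0.001, reach=30.0):
    """1 mm exhaustive-scan oracle for the depth of ignition."""
    best = 0.0
    d = 0.0
    while d <= reach:
        t_req = ff.time_to_ignition(
            ff.plume_temperature(d, donor, ambient, cfg),
            receiver.ic, receiver.ignition_temperature, cfg,
        )
        if t_req <= donor.duration_remaining:
            best = d
        d += step
    return best


class TestDepthOfIgnition:
    def test_expired_donor_ignites_nothing(self, cfg):
        assert ff.depth_of_ignition(flame(dur=0.0), RECEIVER, 30.0, cfg) == 0.0

    def test_plume_below_endotherm_ignites_nothing(self, cfg):
        cold = flame(temp=200.0, dur=100.0)  # whole plume below 260 degC
        assert ff.depth_of_ignition(cold, RECEIVER, 30.0, cfg) == 0.0

    def test_flame_zone_only_when_duration_is_marginal(self, cfg):
        # time to ignite at flame temperature for this receiver
        t_flame = ff.time_to_ignition(950.0, RECEIVER.ic, 260.0, cfg)
        marginal = flame(length=0.5, dur=t_flame * 1.001)
        depth = ff.depth_of_ignition(marginal, RECEIVER, 30.0, cfg)
        assert depth == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize(
        "length,dur,ambient",
        [(0.3, 2.0, 30.0), (0.8, 5.0, 20.0), (1.5, 1.0, 35.0), (0.1, 40.0, 25.0)],
    )
    def test_matches_exhaustive_scan(self, cfg, length, dur, ambient):
        donor = flame(length=length, dur=dur)
        got = ff.depth_of_ignition(donor, RECEIVER, ambient, cfg)
        oracle = scan_depth(donor, RECEIVER, ambient, cfg)
        assert got == pytest.approx(oracle, abs=0.002)  # within one scan step


class TestLeavesIgnited:
    GEOM = ClumpGeometry(clump_diameter=0.25, clump_separation=0.05, leaf_packing=60.0)

    def path(self, length):
        return ff.PlumePathway((0, 0), (0, length), 0.0, length)

    def test_zero_depth_zero_leaves(self):
        assert ff.leaves_ignited(0.0, self.path(2.0), self.GEOM) == 0

    def test_saturation_at_path_length(self):
        full = ff.leaves_ignited(10.0, self.path(1.0), self.GEOM)
        exact = ff.leaves_ignited(1.0, self.path(1.0), self.GEOM)
        assert full == exact

    @pytest.mark.parametrize(
        "depth,path_len,d,sep,packing",
        [
            (0.4, 2.0, 0.25, 0.05, 60), (1.0, 1.0, 0.25, 0.05, 60),
            (0.7, 0.5, 0.1, 0.0, 30), (2.3, 5.0, 0.4, 0.2, 100),
            (0.05, 1.0, 0.3, 0.1, 45),
        ],
    )
    def test_matches_clump_enumeration(self, depth, path_len, d, sep, packing):
        """Enumerate clumps at [k*(d+sep), k*(d+sep)+d) overlapping the
        ignited length — an explicit loop, no closed form."""
        geom = ClumpGeometry(d, sep, packing)
        effective = min(depth, path_len)
        count, k = 0, 0
        while True:
            start = k * (d + sep)
            if start >= effective - 1e-12:
                break
            count += 1
            k += 1
        expected = count * packing
        assert ff.leaves_ignited(depth, self.path(path_len), geom) == expected


def saturating_site(**weather_overrides):
    """One near-surface stratum under still air; every step the full plume
    pathway ignites, so the cohort arithmetic is hand-checkable."""
    site = make_site([make_stratum()])
    weather = make_weather(wind_velocity=0.0, **weather_overrides)
    return site, weather


class TestCohortBookkeeping:
    def test_hand_traced_count_sequence(self, cfg):
        site, weather = saturating_site()
        stratum = site.present()[0]
        fl = stratum_mean_flammability(stratum, weather.dfmc, cfg)
        capacity = leaves_per_plant(stratum)
        pitch = 0.25 + 0.05
        per_step = math.ceil(stratum.crown_height / pitch - 1e-12) * 60  # full pathway
        dur_steps = max(1, round(fl.flame_duration))

        behaviour = ff.run_site(site, weather, cfg)
        ns = [s.strata[ff.Stratum.NEAR_SURFACE] for s in behaviour.trajectory]

        # guard: the scenario really is saturating (plume reach >> pathway)
        donor = flame(length=behaviour.surface.flame_length,
                      dur=behaviour.surface.flame_duration)
        assert ff.depth_of_ignition(donor, fl, weather.air_temperature, cfg) > stratum.crown_height

        # independent bookkeeping oracle: plain cohort list
        cohorts, cum, burning, expected = [], 0, 0, []
        for t in range(1, len(ns) + 1):
            ext = sum(n for e, n in cohorts if e <= t)
            cohorts = [(e, n) for e, n in cohorts if e > t]
            new = min(per_step, capacity - cum) if (cum < capacity and (burning > 0 or t >= 1)) else 0
            if new:
                cohorts.append((t + dur_steps, new))
                cum += new
            burning = burning + new - ext
            expected.append(burning)
        got = [snap.leaves_burning for snap in ns]
        assert got == expected

    def test_conservation_holds_at_every_step(self, cfg, small_study):
        sid = sorted(small_study.sites)[0]
        site, weather = small_study.sites[sid], small_study.weather[sid]
        behaviour = ff.run_site(site, weather, cfg)
        prev = {s: 0 for s in site.strata}
        for state in behaviour.trajectory:
            for stratum, snap in state.strata.items():
                assert snap.leaves_burning == (
                    prev[stratum] + snap.newly_ignited - snap.extinguished
                )
                assert snap.leaves_burning >= 0
                prev[stratum] = snap.leaves_burning

    def test_everything_extinguishes(self, cfg):
        site, weather = saturating_site()
        behaviour = ff.run_site(site, weather, cfg)
        assert not behaviour.truncated
        final = behaviour.trajectory[-1]
        assert all(s.leaves_burning == 0 for s in final.strata.values())
        assert not final.surface_active


class TestRunSite:
    def test_no_strata_reduces_to_surface_flame(self, cfg, weather):
        site = ff.SiteStructure(site_id="bare", strata={}, surface_fuel_load=15.0).validate()
        behaviour = ff.run_site(site, weather, cfg)
        assert behaviour.max_flame_height == pytest.approx(behaviour.surface.flame_height)
        assert behaviour.strata_burnt == frozenset()

    def test_huge_interstrata_gap_blocks_climb(self, cfg):
        canopy = make_stratum(
            traits=make_traits(stratum=ff.Stratum.CANOPY, name="tree",
                               clump_diameter=0.5, clump_separation=0.2),
            stratum=ff.Stratum.CANOPY,
            crown_base_centre_height=100.0, crown_base_edge_height=100.5,
            crown_height=110.0, crown_top_edge_height=108.0, crown_width=4.0,
            plant_separation=8.0,
        )
        site = make_site([make_stratum(), canopy])
        behaviour = ff.run_site(site, make_weather(wind_velocity=0.0), cfg)
        assert ff.Stratum.NEAR_SURFACE in behaviour.strata_burnt
        assert ff.Stratum.CANOPY not in behaviour.strata_burnt

    def test_deterministic(self, cfg):
        site, weather = saturating_site()
        a = ff.run_site(site, weather, cfg)
        b = ff.run_site(site, weather, cfg)
        assert a.trajectory == b.trajectory
        assert a.max_flame_height == b.max_flame_height

    def test_more_surface_fuel_never_lowers_flame_height(self, cfg):
        weather = make_weather(wind_velocity=0.0)
        heights = []
        for load in (5.0, 10.0, 15.0, 20.0):
            site = make_site([make_stratum()], surface_fuel_load=load)
            heights.append(ff.run_site(site, weather, cfg).max_flame_height)
        assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_removing_a_stratum_never_adds_burnt_strata_above(self, cfg):
        ns = make_stratum()
        elevated = make_stratum(
            traits=make_traits(stratum=ff.Stratum.ELEVATED, name="shrub"),
            stratum=ff.Stratum.ELEVATED,
            crown_base_centre_height=0.8, crown_base_edge_height=0.9,
            crown_height=2.0, crown_top_edge_height=1.8, crown_width=1.2,
            plant_separation=2.0,
        )
        mid = make_stratum(
            traits=make_traits(stratum=ff.Stratum.MIDSTOREY, name="acacia",
                               clump_diameter=0.6, clump_separation=0.2),
            stratum=ff.Stratum.MIDSTOREY,
            crown_base_centre_height=2.5, crown_base_edge_height=2.8,
            crown_height=6.0, crown_top_edge_height=5.5, crown_width=2.5,
            plant_separation=5.0,
        )
        weather = make_weather(wind_velocity=0.0)
        with_ladder = ff.run_site(make_site([ns, elevated, mid]), weather, cfg)
        without = ff.run_site(make_site([ns, mid]), weather, cfg)
        above = {ff.Stratum.MIDSTOREY, ff.Stratum.CANOPY}
        assert len(without.strata_burnt & above) <= len(with_ladder.strata_burnt & above)

    def test_wider_canopy_spacing_never_reduces_low_flame_tilt(self, cfg):
        """Lower canopy LAI lets more wind below, tilting low flames more."""
        def tilt(separation):
            canopy = make_stratum(
                traits=make_traits(stratum=ff.Stratum.CANOPY, name="tree",
                                   clump_diameter=0.5, clump_separation=0.2),
                stratum=ff.Stratum.CANOPY,
                crown_base_centre_height=10.0, crown_base_edge_height=10.5,
                crown_height=18.0, crown_top_edge_height=16.0, crown_width=4.0,
                plant_separation=separation,
            )
            profile = ff.wind_profile(make_weather().wind_speed_ms, [canopy], cfg)
            angle = ff.flame_angle(1.0, profile.speed_at(0.3), 0.0, cfg)
            return math.pi / 2 - angle

        assert tilt(12.0) >= tilt(4.0)

    def test_ignition_length_respects_entry_offset(self):
        pw = ff.PlumePathway((0, 1.0), (0, 2.0), 1.0, 1.0)
        assert _ignition_length(0.5, pw) == 0.0   # plume too short to reach entry
        assert _ignition_length(1.4, pw) == pytest.approx(0.4)
        assert _ignition_length(5.0, pw) == pytest.approx(1.0)  # saturates
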