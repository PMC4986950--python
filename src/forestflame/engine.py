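"""Time-stepped flame propagation engine.

The simulator advances in one-second steps. A surface litter flame pilots
the system; each step, every burning stratum recomputes its merged flame
from the number of leaves alight, the flame tilts with the wind at its
height, the plume pathway through crowns is re-cut, new leaves ignite
wherever the plume is hot enough for long enough, and leaves whose flame
duration has elapsed drop out. The bookkeeping identity

    leaves_burning(t) = leaves_burning(t-1) + newly_ignited(t) - extinguished(t)

is asserted every step. Ignition escalates upward: surface -> near-surface
-> elevated -> midstorey -> canopy, with each unburnt stratum tested
against the hottest donor flame beneath it. Convective heat dissipates with
distance, so wide inter-strata gaps stop the climb. The engine is fully
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .config import ModelConfig
from .domain import SiteStructure, Stratum, WeatherRecord
from .leaf import LeafFlammability, stratum_mean_flammability
from .microclimate import leaves_per_plant, wind_profile
from .physics import FlameSegment, PlumePathway, flame_angle, merged_flame_length, plume_pathway, plume_temperature
from .leaf import time_to_ignition
from .surface import SurfaceFire, surface_flame

logger = logging.getLogger("forestflame")

__all__ = [
    "ClumpGeometry",
    "StratumSnapshot",
    "FireState",
    "FireBehaviour",
    "depth_of_ignition",
    "leaves_ignited",
    "run_site",
]

_MAX_REACH = 1.0e4  # m; cap on any ignition distance search


@dataclass(frozen=True)
class ClumpGeometry:
    """Clump layout a plume ignites through (possibly a species-mix mean)."""

    clump_diameter: float
    clump_separation: float
    leaf_packing: float


@dataclass(frozen=True)
class StratumSnapshot:
    leaves_burning: int
    newly_ignited: int
    extinguished: int
    flame_height: float
    flame_length: float
    flame_angle: float


@dataclass(frozen=True)
class FireState:
    """Per-time-step simulator state."""

    t: int
    strata: dict[Stratum, StratumSnapshot]
    surface_active: bool
    ignited_strata: frozenset[Stratum]
    overall_flame_height: float


@dataclass(frozen=True)
class FireBehaviour:
    """Result of one site run."""

    trajectory: tuple[FireState, ...]
    max_flame_height: float
    strata_burnt: frozenset[Stratum]
    donor_flame_heights: dict[str, float]  # per stratum value plus "surface"
    surface: SurfaceFire
    truncated: bool


def depth_of_ignition(
    donor: FlameSegment,
    receiver: LeafFlammability,
    ambient: float,
    config: ModelConfig,
) -> float:
    """Largest distance along the plume axis at which receiver leaves ignite.

    A leaf at distance d ignites if the donor keeps flaming for at least the
    receiver's time-to-ignition at the plume temperature there. Because the
    plume cools monotonically with distance, the qualifying set is an
    interval [0, depth]; the boundary is found by bracketing and bisection.
    Returns 0 when no distance qualifies (donor expired, or the whole plume
    sits below the receiver endotherm or cools too fast).
    """
    dur = donor.duration_remaining
    if dur <= 0 or donor.flame_length <= 0:
        return 0.0

    def needed(d: float) -> float:
        temp = plume_temperature(d, donor, ambient, config)
        return time_to_ignition(temp, receiver.ic, receiver.ignition_temperature, config)

    if needed(0.0) > dur:
        return 0.0
    lo = donor.flame_length
    if needed(lo) > dur:  # only the flame zone itself qualifies
        return lo
    hi = lo * 2.0
    while needed(hi) <= dur:
        hi *= 2.0
        if hi >= _MAX_REACH:
            return _MAX_REACH
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if needed(mid) <= dur:
            lo = mid
        else:
            hi = mid
    return lo


def leaves_ignited(depth: float, pathway: PlumePathway, traits) -> int:
    """Leaf count ignited along a plume pathway.

    ``depth`` is the ignition length measured inside the crown from the
    pathway entry. Clumps of diameter d sit on a pitch of (d + separation)
    along the pathway; every clump the ignited length touches contributes
    its full leaf packing.
    """
    if depth <= 0 or pathway.path_length <= 0:
        return 0
    effective = min(depth, pathway.path_length)
    pitch = traits.clump_diameter + traits.clump_separation
    if pitch <= 0 or traits.leaf_packing <= 0:
        return 0
    n_clumps = math.ceil(effective / pitch - 1e-12)
    return int(round(n_clumps * traits.leaf_packing))


@dataclass
class _StratumState:
    capacity: int
    leaves_burning: int = 0
    cumulative_ignited: int = 0
    cohorts: list[tuple[int, int]] = field(default_factory=list)  # (expiry, n)


def _ignition_length(depth: float, pathway: PlumePathway) -> float:
    """Portion of the pathway, measured from its entry, within reach of the
    ignition depth (which is measured from the flame origin)."""
    if pathway.path_length <= 0:
        return 0.0
    end = min(depth, pathway.entry_distance + pathway.path_length)
    return max(0.0, end - pathway.entry_distance)


def run_site(
    site: SiteStructure,
    weather: WeatherRecord,
    config: ModelConfig,
    record_trajectory: bool = True,
) -> FireBehaviour:
    """Simulate one site burn and return its fire behaviour.

    The surface flame (under the overstorey-sheltered wind) pilots the
    near-surface stratum; the run ends when no flames remain or after
    ``engine.max_steps`` steps (logged as truncation). Burnt strata stop
    sheltering the wind; unburnt foliage above the flames keeps doing so.
    """
    site.validate()
    weather.validate()
    eng = config["engine"]
    dt = float(eng["time_step_s"])
    max_steps = int(eng["max_steps"])
    ambient = weather.air_temperature
    open_wind = weather.wind_speed_ms
    flame_temp = float(config["plume"]["flame_temperature_c"])
    ref_height = float(config["wind_profile"]["reference_height_m"])

    present = site.present()
    flam = {
        st.stratum: stratum_mean_flammability(st, weather.dfmc, config)
        for st in present
    }
    geom = {
        st.stratum: ClumpGeometry(
            clump_diameter=st.weighted([sp.clump_diameter for sp in st.species]),
            clump_separation=st.weighted([sp.clump_separation for sp in st.species]),
            leaf_packing=st.weighted([sp.leaf_packing for sp in st.species]),
        )
        for st in present
    }
    states = {st.stratum: _StratumState(capacity=leaves_per_plant(st)) for st in present}

    profile0 = wind_profile(open_wind, list(present), config)
    surf = surface_flame(
        site.surface_fuel_load, weather.dfmc, profile0.speed_at(ref_height),
        weather.slope, config,
    )

    burnt: set[Stratum] = set()
    donor_heights: dict[str, float] = {"surface": surf.flame_height}
    max_height = surf.flame_height
    trajectory: list[FireState] = []
    truncated = False

    t = 0
    while True:
        t += 1
        if t > max_steps:
            truncated = True
            logger.warning("site %s: run truncated at %d steps", site.site_id, max_steps)
            break
        surface_active = t * dt <= surf.flame_duration
        shelter = [st for st in present if st.stratum not in burnt]
        profile = wind_profile(open_wind, shelter, config)
        surf_seg = (
            FlameSegment(
                origin_height=0.0,
                flame_length=surf.flame_length,
                angle=surf.flame_angle,
                flame_temperature=flame_temp,
                duration_remaining=surf.flame_duration - (t - 1) * dt,
            )
            if surface_active
            else None
        )

        flames: dict[Stratum, FlameSegment] = {}
        snapshots: dict[Stratum, StratumSnapshot] = {}
        any_burning = False
        for st in present:
            s = st.stratum
            state = states[s]
            fl = flam[s]
            new = 0
            seg = None
            if state.leaves_burning > 0:
                merged = merged_flame_length(state.leaves_burning, fl.leaf_flame_length, config)
                origin = st.crown_base_centre_height
                wind_here = profile.speed_at(max(origin, 0.0))
                angle = flame_angle(merged, wind_here, weather.slope, config)
                seg = FlameSegment(origin, merged, angle, flame_temp, fl.flame_duration)
                flames[s] = seg
                if state.cumulative_ignited < state.capacity and merged > 0:
                    pw = plume_pathway(seg, st)
                    depth = depth_of_ignition(seg, fl, ambient, config)
                    n = leaves_ignited(_ignition_length(depth, pw), pw, geom[s])
                    new = min(n, state.capacity - state.cumulative_ignited)
            elif state.cumulative_ignited < state.capacity:
                donors = [f for x, f in flames.items() if x.order < s.order]
                if surf_seg is not None:
                    donors.append(surf_seg)
                donor = max(donors, key=lambda f: f.flame_height, default=None)
                if donor is not None and donor.flame_length > 0:
                    pw = plume_pathway(donor, st)
                    if pw.path_length > 0:
                        depth = depth_of_ignition(donor, fl, ambient, config)
                        n = leaves_ignited(_ignition_length(depth, pw), pw, geom[s])
                        new = min(n, state.capacity - state.cumulative_ignited)

            prev = state.leaves_burning
            extinguished = sum(n for expiry, n in state.cohorts if expiry <= t)
            state.cohorts = [(e, n) for e, n in state.cohorts if e > t]
            if new > 0:
                dur_steps = max(1, int(round(fl.flame_duration / dt)))
                state.cohorts.append((t + dur_steps, new))
                state.cumulative_ignited += new
                burnt.add(s)
            state.leaves_burning = prev + new - extinguished
            assert state.leaves_burning == prev + new - extinguished >= 0, (
                "leaf-count conservation violated"
            )
            if state.leaves_burning > 0:
                any_burning = True
            snapshots[s] = StratumSnapshot(
                leaves_burning=state.leaves_burning,
                newly_ignited=new,
                extinguished=extinguished,
                flame_height=seg.flame_height if seg else 0.0,
                flame_length=seg.flame_length if seg else 0.0,
                flame_angle=seg.angle if seg else 0.0,
            )

        step_height = surf.flame_height if surface_active else 0.0
        for s, seg in flames.items():
            step_height = max(step_height, seg.flame_height)
            key = s.value
            donor_heights[key] = max(donor_heights.get(key, 0.0), seg.flame_height)
        max_height = max(max_height, step_height)

        if record_trajectory:
            trajectory.append(
                FireState(
                    t=t,
                    strata=snapshots,
                    surface_active=surface_active,
                    ignited_strata=frozenset(burnt),
                    overall_flame_height=step_height,
                )
            )
        if not surface_active and not any_burning:
            break

    return FireBehaviour(
        trajectory=tuple(trajectory),
        max_flame_height=max_height,
        strata_burnt=frozenset(burnt),
        donor_flame_heights=donor_heights,
        surface=surf,
        truncated=truncated,
    )
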