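# forestflame

Mechanistic prediction of stand-level flame height in multi-strata eucalypt
forests from species leaf traits and three-dimensional plant structure.

Conventional fire-behaviour models predict flames from the mass of dead
litter on the ground. That works for low fires but says nothing about the
moment a fire climbs off the litter into shrubs, midstorey and tree crowns
— the transition that actually decides fire severity. `forestflame` is a
process simulator for that transition, aimed at fire ecologists and
fire-behaviour researchers who want to ask *"what happens to flame height
if the species mix changes?"* rather than *"what happens if the fuel load
changes?"*.

## The model

A burning leaf is a **donor**: it produces a flame and a convective plume
whose temperature decays with distance along the flame axis. A nearby
**receiver** leaf ignites if the donor keeps flaming longer than the
receiver's time-to-ignition at the plume temperature where it sits. Leaf
ignitability is summarised by the ignitability coefficient

    IC = leaf moisture (%ODW) x thickness (mm) / number of leaf sides

(the larger the IC, the harder the leaf is to ignite), where leaf moisture
is the live/dead mean weighted by the fraction of dead foliage, with dead
foliage at the site's dead-fuel moisture content (DFMC). Flame duration
("sustainability") scales with leaf cross-section (width x thickness), and
single-leaf flame length ("combustibility") with leaf length, width and
moisture.

The simulation advances in one-second steps with the bookkeeping identity

    leaves_burning(t) = leaves_burning(t-1) + newly_ignited(t) - extinguished(t)

per stratum. Each step the merged stratum flame (length ~ per-leaf flame x
n^b, b <= 1) tilts with the local wind, the plume axis cuts a **pathway**
through the crowns above, and the depth of ignition along that pathway sets
how many leaves ignite next. A litter flame (an empirical fuel-load /
moisture / wind relation, clamped to its calibration domain) pilots the
system, and ignition escalates surface -> near-surface -> elevated ->
midstorey -> canopy. Unburnt foliage overhead shelters the flames from the
wind: wind magnitude attenuates exponentially with the cumulative leaf area
index (LAI) above, summarised by the wind reduction factor
WRF = open wind / wind at 1.5 m.

Three treatments replay each site with increasing information:

| treatment | stands for | uses |
|-----------|-----------|------|
| `F`   | surface fuel only | litter flame under the sheltered wind |
| `FS`  | + stand structure | full engine, taxon-group-mean traits, group-norm clump layout |
| `FSL` | + leaf traits     | full engine, species-specific traits and clumps |

Predictions are scored against observed flame-height *intervals* (height of
combustion up to scorch height): signed/absolute error against the interval
median, and the proportion of correct predictions over all sites (PCP) and
over sites with flames >= 1 m (PCP1), with paired t-tests between
treatments. An ensemble LASSO (penalty by random 10-fold cross-validation,
"min" or one-standard-error rule, repeated over many fold allocations)
attributes the FS - FSL prediction differences to donor flammability,
receiver ignitability, overstorey sheltering and exogenous drivers.

A seeded generator manufactures complete synthetic studies (sites, species,
weather, observed intervals) inside field-realistic parameter ranges, so
the whole pipeline runs and tests with no external data.

## Worked example

```
$ forestflame synth --seed 3 --n-sites 6 --out-dir demo
wrote 6 sites to demo

$ forestflame validate --species demo/species.csv --structure demo/structure.csv \
    --weather demo/weather.csv --observations demo/observations.csv --out-dir demo/val
{"F": 4.506, "FS": 2.309, "FSL": 0.0}
```

The printed line is each treatment's mean absolute error (m). On these six
synthetic sites the surface-fuel-only treatment misses by 4.5 m on average
— its mean error is -4.5 m, i.e. it never predicts the large flames — the
structure-only treatment narrows that to 2.3 m, and the fully specified
treatment recovers the (noise-free) truth exactly, because the generator
manufactured the observations from the same fully specified model.
`demo/val/metrics.json` holds ME/MAE with standard errors, PCP and PCP1 per
treatment; `pairs.json` the paired t-tests.

```
$ forestflame simulate --site S001 --species demo/species.csv \
    --structure demo/structure.csv --weather demo/weather.csv --out demo/run
max flame height: 5.30 m
```

`demo/run_summary.json` shows the fire climbed near-surface -> elevated ->
midstorey (donor flame heights 5.30, 1.79 and 2.90 m) from a 0.47 m surface
flame; `demo/run_trajectory.csv` holds the per-second leaf counts and flame
geometry per stratum.

```
$ forestflame sensitivity --species demo/species.csv --structure demo/structure.csv \
    --weather demo/weather.csv --n-runs 20 --k 4 --seed 2 --out demo/ensemble.csv
          predictor  n_included  mean_coef      q2.5     q97.5
     delta_donor_fh          20   0.917733  0.724512  1.027634
         sum_lai_fs          11  -0.148314 -0.169545 -0.127907
               dfmc          11  -2.769732 -3.837482 -1.561328
...
```

The difference between treatments in donor flame height enters every fitted
model — donor flammability dominates the FS - FSL differences — with
overstorey LAI and dead-fuel moisture as secondary influences.

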