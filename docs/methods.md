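# Methods

This note records the model as implemented: its assumptions, the
coefficients that matter, the deliberately open design choices, and what
the synthetic-data tests do and do not demonstrate.

## Model structure and assumptions

The simulator is convection-driven and two-dimensional: all geometry lives
in the vertical transect aligned with the spread direction (x downwind, z
above ground). Radiative preheating, ember transport, smouldering and rate
of spread are out of scope. Plant crowns are symmetric hexagonal
cross-sections built from five measured heights (crown base at centre and
edge, crown top at centre and edge, i.e. crown height and top-edge height)
and a width; a stratum is a single representative plant of its
composition-weighted species mix, centred on the transect. The four strata
(near-surface, elevated, midstorey, canopy) are vertically ordered by crown
height.

One time step (1 s) does, bottom-up per stratum: recompute the merged
flame from the leaves alight; tilt it with the wind at its origin height;
cut the plume pathway through the crown; ignite new leaves over the depth
of ignition; retire leaves whose flame duration has elapsed. An unburnt
stratum is tested against the single hottest donor flame below it (the
tallest flame tip; the surface flame counts as a donor). Each plant is a
finite fuel pool — the total leaf count of its clumps — so every run
terminates when the pool is spent or the pilot expires; a 600-step cap
backstops slow-burning large crowns with a logged truncation.

Leaf-level relations (time to ignition, flame duration, single-leaf flame
length), the flame angle, plume decay, flame merging, the litter pilot
flame and the wind-attenuation coefficient are all configuration entries
in `src/forestflame/data/submodels.yaml`. The shipped values are this
package's own default calibration: each functional form is chosen for the
limits and monotonicities it must honour, with magnitudes set to produce
field-realistic behaviour in dry eucalypt forest (leaf flames of order
0.1 m, litter flames 0.3–1 m, stand flames metres to tens of metres, WRF
2–6 under an intact canopy). The forms are:

* **time to ignition** `t = (a0 + a1 IC) exp(-a2 (T - T_endo))` for plume
  temperature `T` at or above the leaf endotherm, infinite below it.
  Defaults a0 = 0.4 s, a1 = 0.12 s per IC unit, a2 = 0.0045 /degC: a
  typical eucalypt leaf (IC ~ 20) needs ~2.8 s at its endotherm and ~0.1 s
  in the flame zone.
* **flame duration** `d = b0 + b1 (w x t, mm^2) + b2 M` — linear in leaf
  cross-section and (weakly) moisture; ~3 s for a eucalypt leaf.
* **leaf flame length** `L = c1 l (1 + c2 w_mm) exp(-c3 M/100)`, clamped at
  zero; ~0.09 m for a 5 cm leaf at 90 %ODW.
* **flame angle** `theta = arctan(k sqrt(gL) / |u|)` — vertical in still
  air, tilting as the buoyancy/inertia ratio falls; ground slope rotates
  the angle by half its value (upslope spread lays the flame down,
  downslope spread steepens it). Opposing winds mirror the plume; the
  magnitude is used.
* **plume temperature** — flame temperature (950 degC) within the flame,
  then the excess over ambient decays as `(L/d)^5/3`, the classic plume
  similarity exponent.
* **flame merging** `L_n = L_1 n^0.45` — sublinear coalescence of n leaf
  flames.
* **surface (pilot) flame** `L = s1 W exp(-s2 DFMC)(1 + s3 u)` for fine
  fuel load W (t/ha), with duration 20 + 1.5 W seconds, clamped to a
  calibration domain box (2–25 t/ha, DFMC 0.02–0.15, wind 0–3 m/s at
  1.5 m, slope +-30 deg); out-of-domain inputs are clamped to the boundary
  and flagged.
* **wind profile** `u(z) = u_open exp(-0.6 LAI_above(z))`, where a stratum
  part-way overhead contributes the overlapping fraction of its LAI; only
  unburnt strata shelter. WRF = u_open / u(1.5 m).

LAI is assembled bottom-up: one-sided leaf area x leaves per clump x
clumps per crown x crowns per unit ground area. Clumps of diameter d at
pitch (d + separation) give a volumetric packing fraction (d/(d+sep))^3 of
the crown volume (cross-section area x crown width). The ground footprint
of a plant is `max(plant separation, crown width)`: without that bound,
independently sampled wide crowns at small separations stack LAI without
limit (stand LAI ~17, WRF ~1e5, both far outside any field range).

## Treatments

`F` runs only the pilot flame under the LAI-sheltered wind. `FSL` runs the
full engine. `FS` replaces every species' traits — including clump
diameter, separation and leaf packing — with unweighted
monocotyledon/dicotyledon means over the supplied species table (clump
diameter capped at the crown depth so the clump fits the crown). Two
collapse variants were rejected: a single crown-filling clump carrying the
group-mean *per-clump* leaf count leaves a canopy crown with a dozen
leaves, and filling crowns at the group-mean *in-clump leaf density*
imports grass-clump densities into hundred-cubic-metre tree crowns. Using
the group-norm clump layout is bounded in every stratum and makes FS = FSL
exact whenever a site's traits already equal their group means — the
nesting property the treatment comparison relies on. The group means
default to unweighted means over species (a config-visible choice;
abundance weighting would need per-site abundances the inputs do not
carry).

## Validation and sensitivity

Errors are measured against the median of the observed interval;
correctness against the full interval with inclusive bounds. PCP1 uses
sites whose observed median is >= 1 m. Paired t-tests compare per-site
absolute errors (or 0/1 correctness); an exactly constant difference is
reported as degenerate with p = 0 rather than dividing by a zero variance.

The LASSO uses 12 standardised predictors and the FS - FSL flame-height
difference as response. The penalty path is 100 log-spaced values from the
data-derived maximum down three decades; folds are allocated by a seeded
shuffle; the "1se" rule picks the largest penalty within one standard
error of the minimum cross-validated error. Coefficients are reported on
the original predictor scale. Delta predictors are FS minus FSL, except
delta canopy LAI which is FSL minus FS (matching its conventional
definition). Two predictors are provisional constructions: *vertical
continuity* is the negated sum of air gaps between successive occupied
strata, and *surface fine fuel* is the site's surface fuel load. The
ensemble repeats the fit under independent fold allocations (default
1000) and reports inclusion counts and coefficient statistics over the
runs that included each predictor; with a handful of near-identical
coefficients the mean can sit a hair outside the 2.5–97.5% band, so exact
bracketing is not asserted.

## Synthetic data

The generator draws structure, weather and fuel uniformly within
field-realistic ranges for montane eucalypt forest (surface fuel
9.6–24.3 t/ha; wind -21 to 30 km/h signed relative to spread; air
temperature 12.5–37.6 degC; RH 13–63.5%; DFMC 3.6–13.7% ODW; slope -28 to
21 deg, negative = downslope spread), with stratum presence probabilities
0.9/0.75/0.6/0.9 bottom-up and 1–3 species per stratum sampled from
synthetic archetype templates (eucalypt canopy, acacia midstorey,
sclerophyll shrubs, tussock grasses, ferns). Crown heights are re-ordered
to respect the vertical stratum ordering; clump diameters are capped at
the crown depth. Observed intervals are manufactured by running FSL and
widening the prediction by a configurable relative half-width (default
0.25; a configurable fraction of sites instead extend their upper bound to
the next unconsumed stratum base).

Because the generator's truth *is* the FSL model, noise-free recovery
tests (PCP = 1, MAE = 0) demonstrate pipeline correctness — generation,
I/O, treatments and scoring are mutually consistent — not predictive skill
on real vegetation. Independent uniform sampling also ignores trait and
structure correlations in real stands. What the synthetic comparisons do
show is the mechanism ordering: surface-fuel-only predictions cannot
produce multi-strata flames (negative mean error on tall stands), and the
donor-flame-height difference dominates the FS - FSL sensitivity ensemble.

## Numerical choices and degenerate inputs

The depth of ignition exploits monotonicity (the plume only cools with
distance): the qualifying set is an interval, found by doubling bracket
plus 60 bisection iterations, capped at 10 km; tests pin it to a 1 mm
exhaustive scan. Clump counting along a pathway is inclusive — any clump
the ignited length touches contributes its full leaf packing, and a plume
that grazes a crown with positive chord length counts as an intersection.
Leaf counts are integers; cohort durations round to whole steps (minimum
one). Zero wind gives a vertical flame exactly; zero flame length gives an
empty pathway; a site with no strata reduces every treatment to the pilot
flame. Degenerate crown polygons (zero area) and constant LASSO responses
are rejected or return the zero model explicitly.

## Problem sizes

Default test and acceptance sizes: 24 generated sites for the treatment
study, 300 structure-only sites for bulk validation, and a 200-row,
1000-run ensemble for LASSO recovery — sizes at which every statistic in
the acceptance report is stable to the printed precision.

## Known limitations

Single representative plant per stratum (no within-stratum spatial
mosaic); one donor per receiver per step (no heat summation across
simultaneous donors); no radiative transfer; no leaf phosphate or tissue
density effects on ignitability; the litter pilot ignores litter-species
effects; the default calibration is plausible rather than fitted to
laboratory data, so absolute predictions should not be used operationally
without site-specific recalibration of `submodels.yaml`.
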