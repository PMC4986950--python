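# Default sub-model calibration for the forestflame simulator.
#
# Each block names the functional form used, its coefficients (with units in
# the key names) and the valid input ranges where the calibration is trusted.
# All values here are the package's own default calibration: forms are chosen
# for the physical limits and monotonicities they must honour (documented in
# docs/methods.md) and magnitudes are set to give field-realistic flame
# dimensions in dry eucalypt forest. Override any block with a user YAML file.

n_sides:
  # leaf sides exposed to convective heating: a flat lamina heats from two
  # faces, a terete (round) leaf has one continuous surface
  flat: 2
  round: 1

default_traits:
  # fill rules for missing trait values, keyed by functional group
  moisture_odw: {standard: 100.0, mesic: 150.0, very_green: 200.0}
  endotherm_c: {aromatic: 220.0, non_aromatic: 260.0}
  # piloted ignition temperature from silica-free ash content (grasses/ferns);
  # linear relation, provisional calibration
  ash_relation: {intercept_c: 260.0, slope_c_per_pct: -1.5}
  percent_dead: {c4_grass: 0.5, default: 0.0}
  equal_composition_weights: true

time_to_ignition:
  formula: exp_decay_ic
  # t_ig = (base_s + ic_coeff_s * IC) * exp(-temp_decay_per_c * (T - endotherm))
  # for plume temperature T at or above the leaf endotherm; no ignition below.
  base_s: 0.4
  ic_coeff_s: 0.12
  temp_decay_per_c: 0.0045
  valid_ic: [0.0, 120.0]
  provenance: package default calibration

flame_duration:
  formula: linear_area_moisture
  # duration = base_s + area_coeff * (width_mm * thickness_mm) + moisture_coeff * M
  base_s: 0.8
  area_coeff_s_per_mm2: 0.25
  moisture_coeff_s_per_pct: 0.005
  valid_area_mm2: [0.0, 60.0]
  provenance: package default calibration

leaf_flame_length:
  formula: length_width_moisture
  # L = length_coeff * leaf_length_m * (1 + width_coeff * width_mm) * exp(-moisture_decay * M/100)
  length_coeff: 2.2
  width_coeff_per_mm: 0.01
  moisture_decay: 0.35
  valid_length_m: [0.0, 0.5]
  provenance: package default calibration

flame_angle:
  formula: arctan_froude
  # angle = arctan(tilt_coeff * sqrt(g * L) / |u|), vertical at zero wind;
  # ground slope rotates the effective angle by slope_coupling * slope.
  tilt_coeff: 0.6
  slope_coupling: 0.5
  min_angle_rad: 0.05
  provenance: package default calibration

plume:
  # constant flame-zone temperature, then power-law decay of the temperature
  # excess with along-axis distance d: dT(d) = dT_flame * (L/d)^decay_exponent
  flame_temperature_c: 950.0
  decay_exponent: 1.667
  origin: tip          # plume axis emanates from the flame tip direction; alternative: midpoint
  provenance: package default calibration

flame_merge:
  # merged flame length from n burning leaves: L = leaf_flame * n^exponent
  exponent: 0.45
  provenance: package default calibration

wind_profile:
  # exponential attenuation of wind magnitude with cumulative overhead LAI
  extinction_coeff: 0.6
  reference_height_m: 1.5
  provenance: package default calibration

surface_fire:
  # litter-bed flame length from fuel load, dead fuel moisture and near-ground
  # wind, constrained to the approximate domain of the laboratory data behind it
  formula: load_moisture_wind
  length_per_t_ha: 0.045
  dfmc_decay: 8.0
  wind_coeff: 0.4
  duration_base_s: 20.0
  duration_per_t_ha: 1.5
  domain:
    fuel_load_t_ha: [2.0, 25.0]
    dfmc: [0.02, 0.15]
    wind_ms: [0.0, 3.0]
    slope_deg: [-30.0, 30.0]
  provenance: package default calibration (domain box provisional)

engine:
  time_step_s: 1.0
  max_steps: 600
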