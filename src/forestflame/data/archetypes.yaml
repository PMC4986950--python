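# Synthetic species archetypes for the stand generator.
#
# These are synthetic trait templates for the broad functional types of dry
# and wet sclerophyll eucalypt forest (eucalypt canopy trees, acacia
# midstorey, sclerophyll shrubs, tussock grasses and ferns). Each numeric
# entry is a [low, high] sampling range in the units of the trait schema
# (thickness in mm, other lengths in m, moisture in %ODW, percent dead as a
# fraction). They are not measurements of any real flora.

near_surface:
  - name: tussock_grass
    taxon_group: monocotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.15, 0.35]
    leaf_width_m: [0.002, 0.006]
    leaf_length_m: [0.15, 0.45]
    live_moisture_pct: [100.0, 200.0]
    percent_dead: [0.2, 0.6]
    ignition_temp_c: [220.0, 260.0]
    leaf_packing: [60, 160]
    clump_diameter_m: [0.15, 0.4]
    clump_separation_m: [0.0, 0.15]
  - name: low_herb
    taxon_group: dicotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.2, 0.4]
    leaf_width_m: [0.01, 0.03]
    leaf_length_m: [0.02, 0.08]
    live_moisture_pct: [150.0, 200.0]
    percent_dead: [0.0, 0.1]
    ignition_temp_c: [260.0, 260.0]
    leaf_packing: [20, 60]
    clump_diameter_m: [0.1, 0.3]
    clump_separation_m: [0.0, 0.1]

elevated:
  - name: sclerophyll_shrub
    taxon_group: dicotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.25, 0.5]
    leaf_width_m: [0.004, 0.02]
    leaf_length_m: [0.01, 0.06]
    live_moisture_pct: [100.0, 150.0]
    percent_dead: [0.0, 0.2]
    ignition_temp_c: [220.0, 260.0]
    leaf_packing: [30, 90]
    clump_diameter_m: [0.2, 0.6]
    clump_separation_m: [0.05, 0.3]
  - name: fine_leaf_shrub
    taxon_group: dicotyledon
    leaf_form: round
    leaf_thickness_mm: [0.3, 0.6]
    leaf_width_m: [0.001, 0.002]
    leaf_length_m: [0.005, 0.02]
    live_moisture_pct: [100.0, 120.0]
    percent_dead: [0.0, 0.3]
    ignition_temp_c: [220.0, 240.0]
    leaf_packing: [80, 200]
    clump_diameter_m: [0.15, 0.5]
    clump_separation_m: [0.05, 0.25]
  - name: bracken_fern
    taxon_group: monocotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.2, 0.4]
    leaf_width_m: [0.003, 0.01]
    leaf_length_m: [0.05, 0.2]
    live_moisture_pct: [150.0, 200.0]
    percent_dead: [0.1, 0.4]
    ignition_temp_c: [240.0, 260.0]
    leaf_packing: [40, 120]
    clump_diameter_m: [0.3, 0.8]
    clump_separation_m: [0.1, 0.4]

midstorey:
  - name: acacia_midstorey
    taxon_group: dicotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.25, 0.45]
    leaf_width_m: [0.005, 0.02]
    leaf_length_m: [0.04, 0.12]
    live_moisture_pct: [100.0, 150.0]
    percent_dead: [0.0, 0.1]
    ignition_temp_c: [220.0, 260.0]
    leaf_packing: [25, 70]
    clump_diameter_m: [0.4, 1.2]
    clump_separation_m: [0.1, 0.6]
  - name: tea_tree
    taxon_group: dicotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.3, 0.5]
    leaf_width_m: [0.002, 0.006]
    leaf_length_m: [0.008, 0.03]
    live_moisture_pct: [100.0, 130.0]
    percent_dead: [0.0, 0.2]
    ignition_temp_c: [220.0, 240.0]
    leaf_packing: [60, 150]
    clump_diameter_m: [0.3, 0.9]
    clump_separation_m: [0.1, 0.5]

canopy:
  - name: eucalypt_canopy
    taxon_group: dicotyledon
    leaf_form: flat
    leaf_thickness_mm: [0.3, 0.55]
    leaf_width_m: [0.01, 0.035]
    leaf_length_m: [0.08, 0.2]
    live_moisture_pct: [100.0, 150.0]
    percent_dead: [0.0, 0.05]
    ignition_temp_c: [220.0, 240.0]
    leaf_packing: [20, 60]
    clump_diameter_m: [0.5, 1.5]
    clump_separation_m: [0.2, 0.8]
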