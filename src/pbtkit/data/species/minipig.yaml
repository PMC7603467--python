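name: minipig
body_weight: 30.0
haematocrit: 0.42
plasma_pH: 7.4
rbc_pH: 7.2
plasma_composition:
  f_water: 0.93
  f_lipid: 0.005
  f_protein: 0.065
interstitial_composition:
  f_water: 0.92
  f_lipid: 0.005
  f_protein: 0.04
rbc_composition:
  f_water: 0.65
  f_lipid: 0.003
  f_protein: 0.3
organs:
  adipose:
    volume: 6.0
    specific_blood_flow: 0.03
    cellular_composition:
      f_water: 0.15
      f_lipid: 0.8
      f_protein: 0.03
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.1
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  bone:
    volume: 3.0
    specific_blood_flow: 0.03
    cellular_composition:
      f_water: 0.4
      f_lipid: 0.25
      f_protein: 0.2
    intracellular_pH: 7.0
    fraction_vascular: 0.03
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  brain:
    volume: 0.36
    specific_blood_flow: 0.55
    cellular_composition:
      f_water: 0.77
      f_lipid: 0.11
      f_protein: 0.08
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.05
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  gonads:
    volume: 0.045
    specific_blood_flow: 0.1
    cellular_composition:
      f_water: 0.8
      f_lipid: 0.03
      f_protein: 0.15
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  heart:
    volume: 0.15
    specific_blood_flow: 0.8
    cellular_composition:
      f_water: 0.73
      f_lipid: 0.05
      f_protein: 0.18
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  kidney:
    volume: 0.24
    specific_blood_flow: 3.0
    cellular_composition:
      f_water: 0.75
      f_lipid: 0.04
      f_protein: 0.18
    intracellular_pH: 7.0
    fraction_vascular: 0.08
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  large_intestine_wall:
    volume: 0.24
    specific_blood_flow: 0.6
    cellular_composition:
      f_water: 0.75
      f_lipid: 0.06
      f_protein: 0.17
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: portal
  liver:
    volume: 1.05
    specific_blood_flow: 0.25
    cellular_composition:
      f_water: 0.7
      f_lipid: 0.06
      f_protein: 0.2
    intracellular_pH: 7.0
    fraction_vascular: 0.1
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  lung:
    volume: 0.24
    specific_blood_flow: 0.0
    cellular_composition:
      f_water: 0.78
      f_lipid: 0.04
      f_protein: 0.15
    intracellular_pH: 7.0
    fraction_vascular: 0.15
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  muscle:
    volume: 10.5
    specific_blood_flow: 0.03
    cellular_composition:
      f_water: 0.75
      f_lipid: 0.022
      f_protein: 0.2
    intracellular_pH: 7.0
    fraction_vascular: 0.02
    fraction_interstitial: 0.12
    peripheral_blood_flow_fraction: 0.6
    drains_to: venous
  rest:
    volume: 2.4150000000000045
    specific_blood_flow: 0.05
    cellular_composition:
      f_water: 0.7
      f_lipid: 0.1
      f_protein: 0.18
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: venous
  skin:
    volume: 3.0
    specific_blood_flow: 0.08
    cellular_composition:
      f_water: 0.65
      f_lipid: 0.1
      f_protein: 0.25
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.35
    peripheral_blood_flow_fraction: 0.4
    drains_to: venous
  small_intestine_wall:
    volume: 0.44999999999999996
    specific_blood_flow: 0.8
    cellular_composition:
      f_water: 0.75
      f_lipid: 0.06
      f_protein: 0.17
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: portal
  spleen:
    volume: 0.06
    specific_blood_flow: 1.2
    cellular_composition:
      f_water: 0.78
      f_lipid: 0.03
      f_protein: 0.18
    intracellular_pH: 7.0
    fraction_vascular: 0.2
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: portal
  stomach_wall:
    volume: 0.15
    specific_blood_flow: 0.6
    cellular_composition:
      f_water: 0.75
      f_lipid: 0.05
      f_protein: 0.17
    intracellular_pH: 7.0
    fraction_vascular: 0.04
    fraction_interstitial: 0.15
    peripheral_blood_flow_fraction: 0.0
    drains_to: portal
lumen:
- name: stomach
  length: 16.6068502766115
  proximal_radius: 3.063370386334077
  distal_radius: 2.297527789750558
  surface_enhancement_factor: 1.0
  pH: 2.5
  fill_fraction: 0.5
  transit_rate: 0.016666666666666666
- name: duodenum
  length: 16.6068502766115
  proximal_radius: 1.2253481545336309
  distal_radius: 1.148763894875279
  surface_enhancement_factor: 300.0
  pH: 6.0
  fill_fraction: 0.4
  transit_rate: 0.0625
- name: upper_jejunum
  length: 66.427401106446
  proximal_radius: 1.110471765046103
  distal_radius: 1.033887505387751
  surface_enhancement_factor: 250.0
  pH: 6.2
  fill_fraction: 0.4
  transit_rate: 0.015625
- name: lower_jejunum
  length: 66.427401106446
  proximal_radius: 0.9955953755585751
  distal_radius: 0.9573032457293991
  surface_enhancement_factor: 200.0
  pH: 6.4
  fill_fraction: 0.4
  transit_rate: 0.015625
- name: upper_ileum
  length: 49.8205508298345
  proximal_radius: 0.9190111159002231
  distal_radius: 0.8807189860710471
  surface_enhancement_factor: 150.0
  pH: 6.8
  fill_fraction: 0.4
  transit_rate: 0.02083333333333333
- name: lower_ileum
  length: 49.8205508298345
  proximal_radius: 0.8424268562418713
  distal_radius: 0.8041347264126952
  surface_enhancement_factor: 100.0
  pH: 7.2
  fill_fraction: 0.4
  transit_rate: 0.02083333333333333
- name: caecum
  length: 9.9641101659669
  proximal_radius: 2.6804490880423173
  distal_radius: 2.297527789750558
  surface_enhancement_factor: 8.0
  pH: 6.0
  fill_fraction: 0.6
  transit_rate: 0.0075
- name: colon
  length: 79.7128813277352
  proximal_radius: 1.9146064914587981
  distal_radius: 1.9146064914587981
  surface_enhancement_factor: 4.0
  pH: 6.5
  fill_fraction: 0.6
  transit_rate: 0.0009375
gastric_emptying_time: 60.0
small_intestinal_transit_time: 240.0
large_intestinal_transit_time: 1200.0
specific_gfr: 0.2
venous_blood_volume: 1.3499999999999999
arterial_blood_volume: 0.6
portal_vein_volume: 0.15
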