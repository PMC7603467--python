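name: human
body_weight: 73.0
haematocrit: 0.44
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
    volume: 10.95
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
    volume: 7.300000000000001
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
    volume: 1.387
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
    volume: 0.1095
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
    volume: 0.365
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
    volume: 0.584
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
    volume: 0.584
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
    volume: 1.8250000000000002
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
    volume: 0.584
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
    volume: 29.200000000000003
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
    volume: 6.09549999999998
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
    volume: 7.300000000000001
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
    volume: 1.095
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
    volume: 0.146
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
    volume: 0.365
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
  length: 25.0
  proximal_radius: 4.0
  distal_radius: 3.0
  surface_enhancement_factor: 1.0
  pH: 2.0
  fill_fraction: 0.5
  transit_rate: 0.06666666666666667
- name: duodenum
  length: 25.0
  proximal_radius: 1.6
  distal_radius: 1.5
  surface_enhancement_factor: 300.0
  pH: 6.0
  fill_fraction: 0.4
  transit_rate: 0.0625
- name: upper_jejunum
  length: 100.0
  proximal_radius: 1.45
  distal_radius: 1.35
  surface_enhancement_factor: 250.0
  pH: 6.2
  fill_fraction: 0.4
  transit_rate: 0.015625
- name: lower_jejunum
  length: 100.0
  proximal_radius: 1.3
  distal_radius: 1.25
  surface_enhancement_factor: 200.0
  pH: 6.4
  fill_fraction: 0.4
  transit_rate: 0.015625
- name: upper_ileum
  length: 75.0
  proximal_radius: 1.2
  distal_radius: 1.15
  surface_enhancement_factor: 150.0
  pH: 6.8
  fill_fraction: 0.4
  transit_rate: 0.020833333333333332
- name: lower_ileum
  length: 75.0
  proximal_radius: 1.1
  distal_radius: 1.05
  surface_enhancement_factor: 100.0
  pH: 7.2
  fill_fraction: 0.4
  transit_rate: 0.020833333333333332
- name: caecum
  length: 15.0
  proximal_radius: 3.5
  distal_radius: 3.0
  surface_enhancement_factor: 8.0
  pH: 6.0
  fill_fraction: 0.6
  transit_rate: 0.006428571428571429
- name: colon
  length: 120.0
  proximal_radius: 2.5
  distal_radius: 2.5
  surface_enhancement_factor: 4.0
  pH: 6.5
  fill_fraction: 0.6
  transit_rate: 0.0008035714285714287
gastric_emptying_time: 15.0
small_intestinal_transit_time: 240.0
large_intestinal_transit_time: 1400.0
specific_gfr: 0.2
venous_blood_volume: 3.2849999999999997
arterial_blood_volume: 1.46
portal_vein_volume: 0.365
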