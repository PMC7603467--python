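name: monkey
body_weight: 5.0
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
    volume: 0.5
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
    volume: 0.5
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
    volume: 0.075
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
    volume: 0.0075
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
    volume: 0.025
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
    volume: 0.04
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
    volume: 0.04
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
    volume: 0.17500000000000002
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
    volume: 0.04
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
    volume: 2.0
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
    volume: 0.6375000000000007
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
    volume: 0.5
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
    volume: 0.075
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
    volume: 0.01
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
    volume: 0.025
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
  length: 7.283459254414211
  proximal_radius: 1.7895924323556345
  distal_radius: 1.3421943242667258
  surface_enhancement_factor: 1.0
  pH: 2.2
  fill_fraction: 0.5
  transit_rate: 0.03333333333333333
- name: duodenum
  length: 7.283459254414211
  proximal_radius: 0.7158369729422538
  distal_radius: 0.6710971621333629
  surface_enhancement_factor: 300.0
  pH: 6.0
  fill_fraction: 0.4
  transit_rate: 0.08333333333333333
- name: upper_jejunum
  length: 29.133837017656845
  proximal_radius: 0.6487272567289175
  distal_radius: 0.6039874459200266
  surface_enhancement_factor: 250.0
  pH: 6.2
  fill_fraction: 0.4
  transit_rate: 0.020833333333333332
- name: lower_jejunum
  length: 29.133837017656845
  proximal_radius: 0.5816175405155812
  distal_radius: 0.5592476351111357
  surface_enhancement_factor: 200.0
  pH: 6.4
  fill_fraction: 0.4
  transit_rate: 0.020833333333333332
- name: upper_ileum
  length: 21.850377763242633
  proximal_radius: 0.5368777297066903
  distal_radius: 0.5145078243022448
  surface_enhancement_factor: 150.0
  pH: 6.8
  fill_fraction: 0.4
  transit_rate: 0.027777777777777776
- name: lower_ileum
  length: 21.850377763242633
  proximal_radius: 0.4921379188977995
  distal_radius: 0.46976801349335406
  surface_enhancement_factor: 100.0
  pH: 7.2
  fill_fraction: 0.4
  transit_rate: 0.027777777777777776
- name: caecum
  length: 4.370075552648527
  proximal_radius: 1.5658933783111801
  distal_radius: 1.3421943242667258
  surface_enhancement_factor: 8.0
  pH: 6.0
  fill_fraction: 0.6
  transit_rate: 0.015000000000000003
- name: colon
  length: 34.960604421188215
  proximal_radius: 1.1184952702222715
  distal_radius: 1.1184952702222715
  surface_enhancement_factor: 4.0
  pH: 6.5
  fill_fraction: 0.6
  transit_rate: 0.0018750000000000004
gastric_emptying_time: 30.0
small_intestinal_transit_time: 180.0
large_intestinal_transit_time: 600.0
specific_gfr: 0.25
venous_blood_volume: 0.22499999999999998
arterial_blood_volume: 0.1
portal_vein_volume: 0.025
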