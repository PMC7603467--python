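name: beagle
body_weight: 12.0
haematocrit: 0.45
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
    volume: 0.96
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
    volume: 1.2000000000000002
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
    volume: 0.14400000000000002
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
    volume: 0.018000000000000002
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
    volume: 0.06
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
    volume: 0.096
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
    volume: 0.096
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
    volume: 0.42000000000000004
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
    volume: 0.096
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
    volume: 5.28
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
    volume: 1.3260000000000003
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
    volume: 1.2000000000000002
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
    volume: 0.18
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
    volume: 0.024
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
    volume: 0.06
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
  length: 10.895191453479551
  proximal_radius: 2.327113186616938
  distal_radius: 1.7453348899627037
  surface_enhancement_factor: 1.0
  pH: 1.5
  fill_fraction: 0.5
  transit_rate: 0.016666666666666666
- name: duodenum
  length: 10.895191453479551
  proximal_radius: 0.9308452746467752
  distal_radius: 0.8726674449813518
  surface_enhancement_factor: 300.0
  pH: 6.0
  fill_fraction: 0.4
  transit_rate: 0.12499999999999997
- name: upper_jejunum
  length: 43.580765813918205
  proximal_radius: 0.84357853014864
  distal_radius: 0.7854007004832166
  surface_enhancement_factor: 250.0
  pH: 6.2
  fill_fraction: 0.4
  transit_rate: 0.031249999999999993
- name: lower_jejunum
  length: 43.580765813918205
  proximal_radius: 0.7563117856505049
  distal_radius: 0.7272228708177931
  surface_enhancement_factor: 200.0
  pH: 6.4
  fill_fraction: 0.4
  transit_rate: 0.031249999999999993
- name: upper_ileum
  length: 32.68557436043865
  proximal_radius: 0.6981339559850814
  distal_radius: 0.6690450411523696
  surface_enhancement_factor: 150.0
  pH: 6.8
  fill_fraction: 0.4
  transit_rate: 0.04166666666666666
- name: lower_ileum
  length: 32.68557436043865
  proximal_radius: 0.639956126319658
  distal_radius: 0.6108672114869462
  surface_enhancement_factor: 100.0
  pH: 7.2
  fill_fraction: 0.4
  transit_rate: 0.04166666666666666
- name: caecum
  length: 6.537114872087731
  proximal_radius: 2.036224038289821
  distal_radius: 1.7453348899627037
  surface_enhancement_factor: 8.0
  pH: 6.0
  fill_fraction: 0.6
  transit_rate: 0.012857142857142855
- name: colon
  length: 52.296918976701846
  proximal_radius: 1.4544457416355863
  distal_radius: 1.4544457416355863
  surface_enhancement_factor: 4.0
  pH: 6.5
  fill_fraction: 0.6
  transit_rate: 0.001607142857142857
gastric_emptying_time: 60.0
small_intestinal_transit_time: 120.0
large_intestinal_transit_time: 700.0
specific_gfr: 0.25
venous_blood_volume: 0.54
arterial_blood_volume: 0.24
portal_vein_volume: 0.06
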