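name: mouse
body_weight: 0.02
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
    volume: 0.0014000000000000002
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
    volume: 0.002
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
    volume: 0.00032
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
    volume: 3.0e-05
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
    volume: 0.0001
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
    volume: 0.00016
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
    volume: 0.00016
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
    volume: 0.0011
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
    volume: 0.00016
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
    volume: 0.008
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
    volume: 0.002729999999999998
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
    volume: 0.002
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
    volume: 0.0003
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
    volume: 4.0e-05
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
    volume: 0.0001
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
  length: 0.5744937271470624
  proximal_radius: 0.34148539337325856
  distal_radius: 0.25611404502994395
  surface_enhancement_factor: 1.0
  pH: 3.0
  fill_fraction: 0.5
  transit_rate: 0.1
- name: duodenum
  length: 0.5744937271470624
  proximal_radius: 0.13659415734930344
  distal_radius: 0.12805702251497197
  surface_enhancement_factor: 300.0
  pH: 6.0
  fill_fraction: 0.4
  transit_rate: 0.16666666666666666
- name: upper_jejunum
  length: 2.2979749085882495
  proximal_radius: 0.12378845509780623
  distal_radius: 0.11525132026347477
  surface_enhancement_factor: 250.0
  pH: 6.2
  fill_fraction: 0.4
  transit_rate: 0.041666666666666664
- name: lower_jejunum
  length: 2.2979749085882495
  proximal_radius: 0.11098275284630904
  distal_radius: 0.1067141854291433
  surface_enhancement_factor: 200.0
  pH: 6.4
  fill_fraction: 0.4
  transit_rate: 0.041666666666666664
- name: upper_ileum
  length: 1.7234811814411872
  proximal_radius: 0.10244561801197756
  distal_radius: 0.09817705059481183
  surface_enhancement_factor: 150.0
  pH: 6.8
  fill_fraction: 0.4
  transit_rate: 0.055555555555555546
- name: lower_ileum
  length: 1.7234811814411872
  proximal_radius: 0.09390848317764611
  distal_radius: 0.08963991576048037
  surface_enhancement_factor: 100.0
  pH: 7.2
  fill_fraction: 0.4
  transit_rate: 0.055555555555555546
- name: caecum
  length: 0.3446962362882374
  proximal_radius: 0.29879971920160125
  distal_radius: 0.25611404502994395
  surface_enhancement_factor: 8.0
  pH: 6.0
  fill_fraction: 0.6
  transit_rate: 0.03
- name: colon
  length: 2.7575698903058994
  proximal_radius: 0.2134283708582866
  distal_radius: 0.2134283708582866
  surface_enhancement_factor: 4.0
  pH: 6.5
  fill_fraction: 0.6
  transit_rate: 0.00375
gastric_emptying_time: 10.0
small_intestinal_transit_time: 90.0
large_intestinal_transit_time: 300.0
specific_gfr: 0.35
venous_blood_volume: 0.0009
arterial_blood_volume: 0.0004
portal_vein_volume: 0.0001
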