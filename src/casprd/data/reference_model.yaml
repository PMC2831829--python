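name: hela_execution_reconstructed
description: 'Reconstructed HeLa apoptosis-execution network: apoptosome/caspase-9 driven activation of
  caspases-3/-7 under XIAP control with Smac antagonism, ubiquitination-enhanced degradation of XIAP-bound
  caspases, caspase-dependent impairment of synthesis/degradation, and cleavage of an effector-caspase
  FRET-substrate analogue as output. Rate constants and concentrations are reconstructed from published
  whole-cell ODE kinetics of apoptosis execution and typical in-vitro caspase/XIAP kinetics; all values
  are overridable.'
output:
  substrate: substrate
  cleaved: substrate_cleaved
species:
- name: apop_pc9
  mass_kDa: 713.0
  init_uM: 0.0
  apoptosome_containing: true
- name: apop_c9
  mass_kDa: 713.0
  init_uM: 0.0
  apoptosome_containing: true
- name: apop_c9_p10
  mass_kDa: 711.0
  init_uM: 0.0
  apoptosome_containing: true
- name: casp3_pro
  mass_kDa: 32.0
  init_uM: 0.2
- name: casp3
  mass_kDa: 58.0
  init_uM: 0.0
- name: casp7_pro
  mass_kDa: 35.0
  init_uM: 0.045
- name: casp7
  mass_kDa: 60.0
  init_uM: 0.0
- name: xiap
  mass_kDa: 57.0
  init_uM: 0.25
- name: bir12
  mass_kDa: 30.0
  init_uM: 0.0
- name: bir3r
  mass_kDa: 27.0
  init_uM: 0.0
- name: smac
  mass_kDa: 22.0
  init_uM: 0.0
- name: xiap_apop_c9
  mass_kDa: 770.0
  init_uM: 0.0
  apoptosome_containing: true
- name: xiap_casp3
  mass_kDa: 115.0
  init_uM: 0.0
- name: xiap_casp7
  mass_kDa: 117.0
  init_uM: 0.0
- name: bir3r_apop_c9
  mass_kDa: 740.0
  init_uM: 0.0
  apoptosome_containing: true
- name: bir12_casp3
  mass_kDa: 88.0
  init_uM: 0.0
- name: bir12_casp7
  mass_kDa: 90.0
  init_uM: 0.0
- name: smac_xiap
  mass_kDa: 79.0
  init_uM: 0.0
- name: smac_bir12
  mass_kDa: 52.0
  init_uM: 0.0
- name: smac_bir3r
  mass_kDa: 49.0
  init_uM: 0.0
- name: substrate
  mass_kDa: 54.0
  init_uM: 1.0
- name: substrate_cleaved
  mass_kDa: 27.0
  init_uM: 0.0
reactions:
- reactants:
    apop_pc9: 1
  products:
    apop_c9: 1
  k: 0.0012
  tag: c9_autoprocessing
- reactants:
    casp3: 1
    apop_pc9: 1
  products:
    casp3: 1
    apop_c9_p10: 1
  k: 0.2
  tag: c3_feedback_on_c9
- reactants:
    casp3: 1
    apop_c9: 1
  products:
    casp3: 1
    apop_c9_p10: 1
  k: 0.2
  tag: c3_feedback_on_c9
- reactants:
    apop_c9: 1
    casp3_pro: 1
  products:
    apop_c9: 1
    casp3: 1
  k: 0.1
  tag: effector_activation
- reactants:
    apop_c9: 1
    casp7_pro: 1
  products:
    apop_c9: 1
    casp7: 1
  k: 0.1
  tag: effector_activation
- reactants:
    apop_c9_p10: 1
    casp3_pro: 1
  products:
    apop_c9_p10: 1
    casp3: 1
  k: 0.1
  tag: effector_activation
- reactants:
    apop_c9_p10: 1
    casp7_pro: 1
  products:
    apop_c9_p10: 1
    casp7: 1
  k: 0.1
  tag: effector_activation
- reactants:
    casp3: 1
    casp3_pro: 1
  products:
    casp3: 2
  k: 0.1
  tag: c3_autoprocessing
- reactants:
    xiap: 1
    apop_c9: 1
  products:
    xiap_apop_c9: 1
  k: 1.0
  tag: xiap_binding
- reactants:
    xiap_apop_c9: 1
  products:
    xiap: 1
    apop_c9: 1
  k: 0.001
  tag: xiap_unbinding
- reactants:
    xiap: 1
    casp3: 1
  products:
    xiap_casp3: 1
  k: 1.0
  tag: xiap_binding
- reactants:
    xiap_casp3: 1
  products:
    xiap: 1
    casp3: 1
  k: 0.001
  tag: xiap_unbinding
- reactants:
    xiap: 1
    casp7: 1
  products:
    xiap_casp7: 1
  k: 1.0
  tag: xiap_binding
- reactants:
    xiap_casp7: 1
  products:
    xiap: 1
    casp7: 1
  k: 0.001
  tag: xiap_unbinding
- reactants:
    bir3r: 1
    apop_c9: 1
  products:
    bir3r_apop_c9: 1
  k: 1.0
  tag: xiap_binding
- reactants:
    bir3r_apop_c9: 1
  products:
    bir3r: 1
    apop_c9: 1
  k: 0.001
  tag: xiap_unbinding
- reactants:
    bir12: 1
    casp3: 1
  products:
    bir12_casp3: 1
  k: 1.0
  tag: xiap_binding
- reactants:
    bir12_casp3: 1
  products:
    bir12: 1
    casp3: 1
  k: 0.001
  tag: xiap_unbinding
- reactants:
    bir12: 1
    casp7: 1
  products:
    bir12_casp7: 1
  k: 1.0
  tag: xiap_binding
- reactants:
    bir12_casp7: 1
  products:
    bir12: 1
    casp7: 1
  k: 0.001
  tag: xiap_unbinding
- reactants:
    casp3: 1
    xiap: 1
  products:
    casp3: 1
    bir12: 1
    bir3r: 1
  k: 0.1
  tag: xiap_cleavage
- reactants:
    smac: 1
    xiap: 1
  products:
    smac_xiap: 1
  k: 1.0
  tag: smac_binding
- reactants:
    smac_xiap: 1
  products:
    smac: 1
    xiap: 1
  k: 0.0001
  tag: smac_unbinding
- reactants:
    smac: 1
    bir12: 1
  products:
    smac_bir12: 1
  k: 1.0
  tag: smac_binding
- reactants:
    smac_bir12: 1
  products:
    smac: 1
    bir12: 1
  k: 0.0001
  tag: smac_unbinding
- reactants:
    smac: 1
    bir3r: 1
  products:
    smac_bir3r: 1
  k: 1.0
  tag: smac_binding
- reactants:
    smac_bir3r: 1
  products:
    smac: 1
    bir3r: 1
  k: 0.0001
  tag: smac_unbinding
- reactants:
    xiap_apop_c9: 1
  products:
    xiap: 1
  k: 0.0005
  tag: ubiquitin_degradation
- reactants:
    xiap_casp3: 1
  products:
    xiap: 1
  k: 0.0005
  tag: ubiquitin_degradation
- reactants:
    xiap_casp7: 1
  products:
    xiap: 1
  k: 0.0005
  tag: ubiquitin_degradation
- reactants:
    bir3r_apop_c9: 1
  products:
    bir3r: 1
  k: 0.0005
  tag: ubiquitin_degradation
- reactants:
    bir12_casp3: 1
  products:
    bir12: 1
  k: 0.0005
  tag: ubiquitin_degradation
- reactants:
    bir12_casp7: 1
  products:
    bir12: 1
  k: 0.0005
  tag: ubiquitin_degradation
- reactants:
    casp3: 1
    substrate: 1
  products:
    casp3: 1
    substrate_cleaved: 1
  k: 0.2
  tag: substrate_cleavage
- reactants:
    casp7: 1
    substrate: 1
  products:
    casp7: 1
    substrate_cleaved: 1
  k: 0.02
  tag: substrate_cleavage
- reactants: {}
  products:
    casp3_pro: 1
  k: 1.16e-05
  tag: synthesis
- reactants:
    casp3_pro: 1
  products: {}
  k: 5.8e-05
  tag: turnover
- reactants: {}
  products:
    casp7_pro: 1
  k: 2.61e-06
  tag: synthesis
- reactants:
    casp7_pro: 1
  products: {}
  k: 5.8e-05
  tag: turnover
- reactants: {}
  products:
    xiap: 1
  k: 1.45e-05
  tag: synthesis
- reactants:
    xiap: 1
  products: {}
  k: 5.8e-05
  tag: turnover
inputs:
- target: apop_pc9
  amplitude_uM: 0.05
  saturation_rate_per_s: 0.01
  wave_velocity_um_per_s: 0.1
  origin_um: 0.0
- target: smac
  amplitude_uM: 0.45
  saturation_rate_per_s: 0.004
  wave_velocity_um_per_s: 0.1
  origin_um: 0.0
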