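# Three-group cohort design (12 / 11 / 23 subjects, 230 retained volumes)
# with reduced interhemispheric temporal-lobe connectivity in each patient
# group, centred on the ipsilateral hippocampus.
groups:
  - {label: LMTLE, n_subjects: 12}
  - {label: RMTLE, n_subjects: 11}
  - {label: HC, n_subjects: 23}
n_timepoints: 230
base_correlation: 0.35
homotopic_correlation: 0.55
cross_correlation: 0.30
ar1_coefficient: 0.3
random_seed: 17
group_edge_effects:
  - {group: LMTLE, roi_a: L_hippo, roi_b: R_hippo, delta: -0.20}
  - {group: LMTLE, roi_a: L_aMTG, roi_b: R_aMTG, delta: -0.15}
  - {group: LMTLE, roi_a: L_TP, roi_b: R_TP, delta: -0.15}
  - {group: LMTLE, roi_a: L_hippo, roi_b: R_SFG, delta: -0.15}
  - {group: LMTLE, roi_a: L_hippo, roi_b: L_amyg, delta: 0.15}
  - {group: LMTLE, roi_a: L_pTFusC, roi_b: L_aMTG, delta: 0.12}
  - {group: RMTLE, roi_a: R_hippo, roi_b: L_hippo, delta: -0.20}
  - {group: RMTLE, roi_a: R_aMTG, roi_b: L_aMTG, delta: -0.15}
  - {group: RMTLE, roi_a: R_TP, roi_b: L_TP, delta: -0.15}
  - {group: RMTLE, roi_a: R_hippo, roi_b: L_SFG, delta: -0.15}
  - {group: RMTLE, roi_a: R_hippo, roi_b: R_amyg, delta: 0.15}
  - {group: RMTLE, roi_a: R_pTFusC, roi_b: R_aMTG, delta: 0.12}
clinical_model:
  LMTLE:
    age: {mean: 25.17, sd: 3.69}
    male_fraction: 0.75
    onset_age: {mean: 16.42, sd: 8.61}
    duration: {mean: 12.83, sd: 8.68}
  RMTLE:
    age: {mean: 29.25, sd: 9.92}
    male_fraction: 0.545
    onset_age: {mean: 19.09, sd: 8.81}
    duration: {mean: 12.73, sd: 6.53}
  HC:
    age: {mean: 31.82, sd: 10.25}
    male_fraction: 0.565
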