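# Default cohort spec: group sizes, duration/clinical distributions and
# subcortical shifts shaped like the reference cohort tables; cascade
# magnitudes are free parameters chosen for testability.
n_td: 69
n_et: 71
n_hc: 80
n_regions: 16
vertices_per_region: 64
baseline_mean: 2.5
noise_sd: 0.10
smoothing_fwhm: 2.5
duration_dist:
  TD: [9.28, 7.16]
  ET: [16.41, 12.48]
# single-source cascade: TP.R leads all three targets by 5 years, with
# staggered saturations/rates so the targets' trajectories stay distinct
cascade:
  - {source: TP.R, target: PreCG.L, effect_rate: 0.06, lag: 5.0, saturation: 10.0}
  - {source: TP.R, target: PCUN.R, effect_rate: 0.075, lag: 5.0, saturation: 15.0}
  - {source: TP.R, target: EC.L, effect_rate: 0.09, lag: 5.0, saturation: 20.0}
subcortical_baselines:
  Pallidum.L: 1898.06
  Pallidum.R: 1865.46
  Thalamus.L: 7004.12
  Thalamus.R: 7003.37
subcortical_noise_sd:
  Pallidum.L: 231.29
  Pallidum.R: 257.89
  Thalamus.L: 699.08
  Thalamus.R: 648.91
subcortical_effects:
  Pallidum.L: {TD: 151.13}
  Pallidum.R: {TD: 126.62}
  Thalamus.L: {ET: -244.44}
  Thalamus.R: {ET: -432.40}
clinical_means:
  TD:
    MoCA: [23.36, 3.04]
    MMSE: [27.57, 1.46]
    HAM_A: [15.42, 9.20]
    HAM_D: [16.59, 9.91]
    VHI: [25.51, 22.09]
  ET:
    MoCA: [21.38, 4.88]
    MMSE: [26.96, 2.36]
    HAM_A: [10.42, 7.60]
    HAM_D: [11.35, 7.41]
    VHI: [7.62, 18.73]
age_dist:
  TD: [63.62, 6.66]
  ET: [65.31, 7.91]
  HC: [63.84, 5.16]
female_fraction:
  TD: 0.4638
  ET: 0.5493
  HC: 0.5375
education_dist:
  TD: [14.13, 10.51]
  ET: [13.61, 4.66]
  HC: [12.98, 5.30]
hy_stage_probs: [0.10, 0.19, 0.50, 0.21]
region_names:
  - TP.R
  - PreCG.L
  - PCUN.R
  - EC.L
  - MOF.R
  - CUN.L
  - SFG.R
  - IPL.R
  - STG.L
  - MTG.L
  - SPG.L
  - FG.L
  - LING.L
  - RACC.L
  - CACC.R
  - ICC.R
seed: 0
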