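# Published model inputs: second-line pemigatinib vs. mFOLFOX vs. 5-FU for
# advanced intrahepatic cholangiocarcinoma with FGFR2 fusions/rearrangements,
# Taiwan NHIA perspective, costs in 2022 NT$, survival time in months.
settings:
  horizon_years: 5.0
  cycle_length_years: 0.08333333333333333   # monthly cycles
  annual_discount_rate: 0.03
  wtp_per_qaly: 2928570.0                   # 3x forecast 2022 GDP per capita
  half_cycle_correction: true

utilities:
  u_pf: 0.76
  u_pd: 0.68
  disutility_ae: 0.16        # grade >=3 adverse events, first cycle by default
  disutility_iv: 0.025       # intravenous/subcutaneous administration route
  ae_duration_mode: first_cycle

costs:
  supportive_care_per_year: 497710.0
  genetic_testing_fee: 30000.0
  testing_fee_policy: intervention_only      # FGFR2 testing gates pemigatinib
  nonmedication_conversion_factor: 1.0       # scenario value 0.9

arms:
  pemigatinib:
    os:  {family: weibull,   params: [22.065, 1.536], label: "OS pemigatinib (FIGHT-202)"}
    pfs: {family: lognormal, params: [1.962, 0.971],  label: "PFS pemigatinib (FIGHT-202)"}
    medication_cost_per_year: 4336200.0      # NT$17,820/day highest listing price
    nonmedication_cost_per_year: 291576.0
    ae_grade3_proportion: 0.56
    iv_administered: false
    requires_genetic_testing: true
  mfolfox:
    os:  {family: lognormal, params: [1.834, 0.873], label: "OS mFOLFOX (ABC-06)"}
    pfs: {family: lognormal, params: [1.430, 0.754], label: "PFS mFOLFOX (ABC-06)"}
    medication_cost_per_year: 412087.0
    nonmedication_cost_per_year: 856986.0
    ae_grade3_proportion: 0.54
    iv_administered: true
    requires_genetic_testing: false
  5fu:
    os:  {family: lognormal, params: [1.764, 0.816], label: "OS 5-FU (NIFTY)"}
    pfs: {family: lognormal, params: [0.8, 1.067],   label: "PFS 5-FU (NIFTY)"}
    medication_cost_per_year: 177759.0
    nonmedication_cost_per_year: 856986.0
    ae_grade3_proportion: 0.18
    iv_administered: true
    requires_genetic_testing: false

intervention: pemigatinib
comparators: [mfolfox, 5fu]
seed: 2022

# Deterministic ranges (95% CI for survival parameters, +/-25% or stated
# bounds otherwise) and probabilistic distributions per parameter.
# gamma_ms(mean, sd) is moment-matched to shape/scale.
sensitivity:
  os_pemigatinib_scale:
    paths: [[arms, pemigatinib, os, params, 0]]
    dsa: [17.486, 27.843]
    psa: {dist: normal, args: [22.065, 2.619], positive: true}
  os_pemigatinib_shape:
    paths: [[arms, pemigatinib, os, params, 1]]
    dsa: [1.184, 1.993]
    psa: {dist: normal, args: [1.536, 0.204], positive: true}
  os_mfolfox_intercept:
    paths: [[arms, mfolfox, os, params, 0]]
    dsa: [1.642, 2.023]
    psa: {dist: normal, args: [1.834, 0.098]}
  os_mfolfox_scale:
    paths: [[arms, mfolfox, os, params, 1]]
    dsa: [0.742, 1.027]
    psa: {dist: normal, args: [0.873, 0.072], positive: true}
  os_5fu_intercept:
    paths: [[arms, 5fu, os, params, 0]]
    dsa: [1.586, 1.943]
    psa: {dist: normal, args: [1.764, 0.091]}
  os_5fu_scale:
    paths: [[arms, 5fu, os, params, 1]]
    dsa: [0.691, 0.965]
    psa: {dist: normal, args: [0.816, 0.07], positive: true}
  pfs_pemigatinib_intercept:
    paths: [[arms, pemigatinib, pfs, params, 0]]
    dsa: [1.76, 2.164]
    psa: {dist: normal, args: [1.962, 0.103]}
  pfs_pemigatinib_scale:
    paths: [[arms, pemigatinib, pfs, params, 1]]
    dsa: [0.82, 1.15]
    psa: {dist: normal, args: [0.971, 0.084], positive: true}
  pfs_mfolfox_intercept:
    paths: [[arms, mfolfox, pfs, params, 0]]
    dsa: [1.265, 1.595]
    psa: {dist: normal, args: [1.43, 0.084]}
  pfs_mfolfox_scale:
    paths: [[arms, mfolfox, pfs, params, 1]]
    dsa: [0.643, 0.885]
    psa: {dist: normal, args: [0.754, 0.062], positive: true}
  pfs_5fu_intercept:
    paths: [[arms, 5fu, pfs, params, 0]]
    dsa: [0.57, 1.031]
    psa: {dist: normal, args: [0.8, 0.118]}
  pfs_5fu_scale:
    paths: [[arms, 5fu, pfs, params, 1]]
    dsa: [0.91, 1.251]
    psa: {dist: normal, args: [1.067, 0.087], positive: true}
  genetic_testing_fee:
    paths: [[costs, genetic_testing_fee]]
    dsa: [22500.0, 37500.0]
    psa: {dist: uniform, args: [22500.0, 37500.0]}
  medication_cost_pemigatinib:
    paths: [[arms, pemigatinib, medication_cost_per_year]]
    dsa: [3252150.0, 5420250.0]
    psa: {dist: uniform, args: [3252150.0, 5420250.0]}
  medication_cost_mfolfox:
    paths: [[arms, mfolfox, medication_cost_per_year]]
    dsa: [309065.0, 515108.0]
    psa: {dist: gamma_ms, args: [412087.0, 617747.0]}
  medication_cost_5fu:
    paths: [[arms, 5fu, medication_cost_per_year]]
    dsa: [133320.0, 222199.0]
    psa: {dist: gamma_ms, args: [177759.0, 282466.0]}
  nonmedication_cost_pemigatinib:
    paths: [[arms, pemigatinib, nonmedication_cost_per_year]]
    dsa: [218682.0, 364470.0]
    psa: {dist: gamma_ms, args: [291576.0, 691057.0]}
  nonmedication_cost_chemotherapy:
    paths:
      - [arms, mfolfox, nonmedication_cost_per_year]
      - [arms, 5fu, nonmedication_cost_per_year]
    dsa: [642740.0, 1071233.0]
    psa: {dist: gamma_ms, args: [856986.0, 1067455.0]}
  supportive_care_cost:
    paths: [[costs, supportive_care_per_year]]
    dsa: [373283.0, 622138.0]
    psa: {dist: gamma_ms, args: [497710.0, 576562.0]}
  utility_pf:
    paths: [[utilities, u_pf]]
    dsa: [0.57, 0.95]
    psa: {dist: beta, args: [4.7, 1.5]}
  utility_pd:
    paths: [[utilities, u_pd]]
    dsa: [0.51, 0.85]
    psa: {dist: beta, args: [29.0, 13.6]}
  disutility_iv:
    paths: [[utilities, disutility_iv]]
    dsa: [0.0188, 0.0313]
    psa: {dist: fixed}
  disutility_ae:
    paths: [[utilities, disutility_ae]]
    dsa: [0.12, 0.2]
    psa: {dist: beta, args: [36.0, 193.0]}
  discount_rate:
    paths: [[settings, annual_discount_rate]]
    dsa: [0.0, 0.05]
    psa: {dist: fixed}
  time_horizon:
    paths: [[settings, horizon_years]]
    dsa: [3.0, 15.0]
    psa: {dist: fixed}
  ae_proportion_pemigatinib:
    paths: [[arms, pemigatinib, ae_grade3_proportion]]
    dsa: [0.42, 0.7]
    psa: {dist: fixed}
  ae_proportion_mfolfox:
    paths: [[arms, mfolfox, ae_grade3_proportion]]
    dsa: [0.405, 0.675]
    psa: {dist: fixed}
  ae_proportion_5fu:
    paths: [[arms, 5fu, ae_grade3_proportion]]
    dsa: [0.135, 0.225]
    psa: {dist: fixed}
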