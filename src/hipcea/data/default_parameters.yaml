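# Decision-model parameters for the femoral-neck-fracture cost-effectiveness
# model (Japanese public-payer perspective, 2022 yen).
#
# SB-THA transition probabilities are annual, by 5-year age band; BHA and
# DM-THA probabilities are derived from the relative risks below.  Entries
# with `rule_range: true` carry only a point estimate and receive the
# SE = 0.2 x point, point +/- 1.96 SE range at load time.  Entries with
# only a point are fixed (not varied in sensitivity analyses).  `derived`
# marks composite utilities recomputed from components at run time.

transition_probabilities:
  p_dis_sb_65: {point: 0.0240, rule_range: true}
  p_dis_sb_70: {point: 0.0235, rule_range: true}
  p_dis_sb_75: {point: 0.0215, rule_range: true}
  p_dis_sb_80: {point: 0.0190, rule_range: true}
  p_dis_sb_85: {point: 0.0132, rule_range: true}
  p_rev_dis_sb_65: {point: 0.0097, rule_range: true}
  p_rev_dis_sb_70: {point: 0.0103, rule_range: true}
  p_rev_dis_sb_75: {point: 0.0086, rule_range: true}
  p_rev_dis_sb_80: {point: 0.0067, rule_range: true}
  p_rev_dis_sb_85: {point: 0.0040, rule_range: true}
  p_rev_nondis_sb_65: {point: 0.0211, rule_range: true}
  p_rev_nondis_sb_70: {point: 0.0225, rule_range: true}
  p_rev_nondis_sb_75: {point: 0.0187, rule_range: true}
  p_rev_nondis_sb_80: {point: 0.0146, rule_range: true}
  p_rev_nondis_sb_85: {point: 0.0087, rule_range: true}

relative_risks:
  rr_dis_dm_vs_sb: {point: 0.17, low: 0.04, high: 0.79}
  rr_dis_dm_vs_bha: {point: 0.41, low: 0.19, high: 0.87}
  rr_rev_dis_bha_vs_dm: {point: 7.16, low: 2.18, high: 23.58}
  rr_rev_nondis_bha_vs_dm: {point: 0.87, low: 0.40, high: 1.88}
  rr_rev_dis_dm_vs_sb: {point: 0.40, low: 0.27, high: 0.59}
  rr_rev_nondis_dm_vs_sb: {point: 0.93, low: 0.75, high: 1.16}

disutilities:
  d_dislocation: {point: -0.110, low: -0.153, high: -0.067}
  d_r_tha: {point: -0.185, low: -0.258, high: -0.112}
  d_rr_tha: {point: -0.287, low: -0.400, high: -0.174}

utilities:
  u_well_bha: {point: 0.820, low: 0.660, high: 0.980}
  u_well_sb: {point: 0.870, low: 0.720, high: 1.000}
  u_well_dm: {point: 0.870, low: 0.720, high: 1.000}
  u_well_r_tha: {point: 0.685, low: 0.535, high: 0.835, derived: true}
  u_well_rr_tha: {point: 0.583, low: 0.433, high: 0.733, derived: true}

costs:
  # mean of closed (42,738) and open (398,620) reduction for hip dislocation
  c_dislocation_event: {point: 220679, low: 134173, high: 307185}
  c_implant_bha: {point: 572000}
  c_implant_sb: {point: 611000}
  c_implant_dm: {point: 714000}
  fee_bha: {point: 195000}
  fee_sb: {point: 376900}
  fee_dm: {point: 376900}
  fee_r_tha: {point: 548100}
  c_initial_bha: {point: 2122628, low: 1290558, high: 2954698}
  c_initial_sb: {point: 2191285, low: 1332301, high: 3050269}
  c_initial_dm: {point: 2191285, low: 1332301, high: 3050269}
  c_well_annual: {point: 1399413, low: 1052656, high: 1746170}
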