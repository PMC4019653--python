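{
 "constants": {
  "k_serg": 18.7589,
  "k_derg": 18.7589,
  "k_sdrg": 56.2767,
  "k_sdrg_drg": 1.87589,
  "J_drg": 0.5,
  "k_ddrg": 56.2767,
  "k_sd": 15.00712,
  "J_sd": 0.5,
  "k_dd": 37.5178,
  "k_asd": 93.7945,
  "k_did": 18.7589,
  "k_dd_k": 18.7589,
  "k_prb_d": 65.65615,
  "k_prb_dk": 65.65615,
  "k_prb_e": 7.50356,
  "k_prb_a": 18.7589,
  "k_dprb": 15.00712,
  "k_prb2_e": 18.7589,
  "k_prb2_a": 18.7589,
  "k_dprb2": 9.37945,
  "k_as_fe": 187.589,
  "k_di_fe": 1.87589,
  "k_de2f_rb": 0.375178,
  "k_se2f_basal": 1.500712,
  "k_se2f": 6.753204,
  "J_se2f": 3.0,
  "k_pe2f_a": 0.281384,
  "k_pe2f_b": 112.5534,
  "k_dpe2f": 1.87589,
  "k_de2f": 0.375178,
  "k_de2f_p": 0.375178,
  "k_de2f_20": 75.0356,
  "k_de2f_h1": 75.0356,
  "k_se_basal": 0.093795,
  "k_se": 5.62767,
  "k_de": 4.689725,
  "k_de_a": 15.00712,
  "k_ase": 93.7945,
  "k_die": 18.7589,
  "k_de_k": 1.87589,
  "k_ski": 7.50356,
  "k_dki": 2.813835,
  "k_dki_d": 3.75178,
  "k_dki_e": 37.5178,
  "k_dki_a": 9.37945,
  "k_dki_b": 0.937945,
  "k_sa_basal": 0.018759,
  "k_sa_e2f": 1.125534,
  "k_sa_ab": 2.251068,
  "k_da": 0.375178,
  "k_da_20": 431.4547,
  "k_da_h1": 168.8301,
  "k_asa": 46.89725,
  "k_dia": 18.7589,
  "k_sb_basal": 0.018759,
  "k_sb_e2f": 1.125534,
  "k_sb_ab": 5.62767,
  "k_sb_b": 0.750356,
  "k_db": 0.187589,
  "k_db_20": 159.45065,
  "k_db_h1": 7.50356,
  "k_wee_basal": 0.187589,
  "k_wee_b": 187.589,
  "k_25_basal": 0.093795,
  "k_25_b": 75.0356,
  "k_aw": 37.5178,
  "J_aw": 0.01,
  "k_iw_a": 24.38657,
  "k_iw_b": 11.25534,
  "J_iw": 0.01,
  "k_a25_b": 150.0712,
  "k_a25_a": 0.375178,
  "J_a25": 0.01,
  "k_i25": 28.13835,
  "J_i25": 0.01,
  "k_ah1": 22.51068,
  "k_ah1_20": 112.5534,
  "J_ah1": 0.03,
  "k_ih1_basal": 0.562767,
  "k_ih1_d": 0.0,
  "k_ih1_e": 168.8301,
  "k_ih1_a": 844.1505,
  "k_ih1_b": 75.0356,
  "J_ih1": 0.03,
  "k_s20_basal": 0.187589,
  "k_s20_a": 1.87589,
  "k_s20_b": 5.62767,
  "k_d20": 3.75178,
  "k_a20": 56.2767,
  "J_a20": 0.05,
  "k_i20": 18.7589,
  "J_i20": 0.05,
  "k_d20a": 3.75178,
  "k_aie": 37.5178,
  "J_aie": 0.05,
  "k_iie": 11.25534,
  "J_iie": 0.05,
  "k_atf": 15.00712,
  "J_atf": 0.05,
  "k_itf": 6.753204,
  "k_itf_b": 15.00712,
  "k_itf_20": 0.0,
  "J_itf": 0.05
 },
 "cyclinA_cdk2_synthesis_fraction": 0.8,
 "solver": {
  "rtol": 1e-08,
  "atol": 1e-10
 },
 "meta": {
  "model": "cdkcycle combined 25-ODE mammalian cell-cycle model",
  "version": "0.1.0",
  "time_unit": "fraction of cell cycle time Tc",
  "Tc_hours": 30.0,
  "concentration_unit": "arbitrary"
 }
}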