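{
 "description": "synthetic reference parameter set constructed by scripts/make_reference.py (checklist-margin anneal, seed 20220613)",
 "parameters": {
  "k_pB": 3.6723506734724656,
  "k_rB": 2.1952056447434067,
  "k_dB": 0.30712071846976174,
  "Q10_B": 2.8247102326356663,
  "a_E": 0.3422352079762908,
  "d_E": 0.7459076584569666,
  "b_E": 0.016633697914062676,
  "w_E": 3.9439452344403083,
  "rho_E": 0.021102633785601538,
  "d_EC": 0.0,
  "Q10_E": 0.19178022728917615,
  "C_dark": 1.0,
  "C_light": 0.013308049581467621,
  "eps_C": 0.8006570367344779,
  "tau_C": 0.1,
  "a_P": 1.9032183059066763,
  "K_E": 0.41502080313616196,
  "h_E": 2.0,
  "d_P": 0.3750469380296078,
  "beta_B": 14.198579673794697,
  "beta_C": 27.389519748349326,
  "Y0": 2.6246057349668934,
  "K_C": 0.4171424555590062,
  "v0": 0.0033186913863204642,
  "v_max": 0.055754970748995575,
  "K_G": 1.751763686978053,
  "n_G": 6.0,
  "K_Bg": 0.03990376331511418,
  "K_Eg": 9.448743515839038,
  "K_Yg": 0.14796499141386263,
  "H0": 0.5
 },
 "genotype_gains": {
  "PHYBox:g_B": 1.5,
  "ELF3ox:g_E": 2.041580654790265,
  "cop1-4:g_C": 0.028176730094002338,
  "COP1-OE:g_C": 1.5,
  "PIF4ox:g_P": 20.000000000000004,
  "pif4:g_P": 0.6,
  "pifq:g_P": 0.15
 }
}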