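# Crassostrea gigas, Pouvreau-style standard-model parameter set.
# No maturity thresholds or ageing block: post-metamorphic simulation only.
name: c_gigas_std
T_ref: 293.1
T_A: 5800.0
T_L: 281.0
T_AL: 75000.0
T_H: 300.0
T_AH: 30000.0
z: 4.29
p_Am: 315.0
kap_X: 0.75
kap_P: 0.05
v: 0.18
kap: 0.45
kap_R: 0.75
p_M: 44.0
p_T: 0.0
k_J: 0.002
E_G: 3900.0
del_M: 0.18
K_X: 3.29
aux:
  d_V: 0.09
  d_E: 0.09
  mu_E: 550000.0
  w_E: 23.9
  w_V: 23.9
  dw_ww_ratio: 0.018
  s_M_ref: 1.0
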