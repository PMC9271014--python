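# Crassostrea (Magallana) gigas, asj model, AmP-style parameter set.
name: c_gigas_amp
T_ref: 293.1
T_A: 5800.0
T_L: 281.0
T_AL: 75000.0
T_H: 300.0
T_AH: 30000.0
z: 1.18
F_m: 30.4
p_Am: 372.0
kap_X: 0.3259
kap_P: 0.2279
v: 0.0054
kap: 0.26
kap_R: 0.95
p_M: 17.35
p_T: 0.0
k_J: 0.002
E_G: 2374.0
E_Hb: 1.78e-4
E_Hs: 1.858e-4
E_Hj: 2.076e-2
E_Hp: 1.778
h_a: 1.03e-9
s_g: 0.0001
del_Mb: 0.87
del_M: 0.20
K_X: 3.29
aux:
  d_V: 0.09
  d_E: 0.09
  mu_E: 550000.0
  w_E: 23.9
  w_V: 23.9
  dw_ww_ratio: 0.018
  s_M_ref: 4.8
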