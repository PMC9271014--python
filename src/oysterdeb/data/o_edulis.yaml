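# Ostrea edulis (European flat oyster), asj model.
# p_Am and v are the fully accelerated values; aux.s_M_ref is the
# reference acceleration factor used to recover the embryo/larval base.
name: o_edulis
T_ref: 293.1
T_A: 5000.0
T_L: 286.0
T_AL: 23000.0
T_H: 303.0
T_AH: 55610.0
z: 1.06
F_m: 13.86
p_Am: 91.0
kap_X: 0.8
kap_P: 0.1
v: 0.020
kap: 0.92
kap_R: 0.45
p_M: 15.68
p_T: 0.0
k_J: 0.002
E_G: 2374.0
E_Hb: 5.002e-4
E_Hr: 5.621e-4
E_Hs: 4.025e-3
E_Hj: 8.637e-1
E_Hp: 32.0
h_a: 6.224e-10
s_g: 0.0001
del_Mb: 0.6992
del_M: 0.397
K_X: 1.84
aux:
  d_V: 0.09
  d_E: 0.09
  mu_E: 550000.0
  w_E: 23.9
  w_V: 23.9
  dw_ww_ratio: 0.015
  s_M_ref: 5.9
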