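coef_bend: 1.1185803664543823
coef_intercept: 19.64531964972344
coef_slide: 7.10838697255285
coef_stop: 0.10722467123936175
nn_dg:
  AA: -1.0
  AC: -1.44
  AG: -1.28
  AT: -0.88
  CA: -1.45
  CC: -1.84
  CG: -2.17
  CT: -1.28
  GA: -1.3
  GC: -2.24
  GG: -1.84
  GT: -1.44
  TA: -0.58
  TC: -1.3
  TG: -1.45
  TT: -1.0
pwm_counts:
  A:
  - 61
  - 16
  - 352
  - 3
  - 354
  - 268
  - 360
  - 222
  - 155
  - 56
  - 83
  - 82
  - 82
  - 68
  - 77
  C:
  - 145
  - 46
  - 0
  - 10
  - 0
  - 0
  - 3
  - 2
  - 44
  - 135
  - 147
  - 127
  - 118
  - 107
  - 101
  G:
  - 152
  - 18
  - 2
  - 2
  - 5
  - 0
  - 20
  - 44
  - 157
  - 150
  - 128
  - 128
  - 128
  - 139
  - 140
  T:
  - 31
  - 309
  - 35
  - 374
  - 30
  - 121
  - 6
  - 121
  - 33
  - 48
  - 31
  - 52
  - 61
  - 75
  - 71
pwm_length: 15
pwm_pseudocount: 1.0
residual_sd_sigma: 0.2
window_length: 26
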