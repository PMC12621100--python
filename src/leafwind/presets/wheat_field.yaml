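description: >
  Field-grown wheat flag leaf for steady-state within-canopy profile
  simulations.  Michaelis constants keep the tobacco-calibrated defaults (a
  wheat-specific override slot: edit Kc25/Ko25 here).  Dynamic time
  constants are irrelevant at steady state and keep the tomato values.

photo:
  Vcmax25: 140.0        # umol CO2 m-2 s-1
  Jmax25: 220.0         # umol m-2 s-1
  Rd25: 0.9             # umol CO2 m-2 s-1
  gm25: 5.0             # umol m-2 s-1 Pa-1
  AbsPAR: 0.86
  Curv: 0.70
  f_spectral: 0.15
  Kc25: 404.9           # umol mol-1
  Ko25: 278.4           # mmol mol-1
  GammaStar25: 42.75    # umol mol-1
  O: 210.0              # mmol mol-1
  tauA_inc: 300.0
  tauA_dec: 1.0
  Ea_Vcmax: 65330.0
  Ea_Jmax: 43540.0
  Ea_Rd: 46390.0
  Ea_Kc: 79430.0
  Ea_Ko: 36380.0
  Ea_GammaStar: 37830.0
  Ea_gm: 49600.0
  Hd_gm: 437400.0
  dS_gm: 1400.0

stomatal:
  g0: 0.02              # mol m-2 s-1
  g1: 7.38
  D0: 2.0               # kPa
  tauG_inc: 900.0
  tauG_dec: 450.0

energy:
  AbsShortwave: 0.50
  emissivity: 0.95
  k_heat: 280.0
  ksun: 0.465658
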