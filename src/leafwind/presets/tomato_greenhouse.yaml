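description: >
  Greenhouse tomato leaf: FvCB biochemistry with finite mesophyll
  conductance, Leuning stomatal model, dynamic induction/relaxation time
  constants for assimilation and stomata.  Temperature-response constants
  are the tobacco-calibrated Arrhenius / peaked-Arrhenius sets standard in
  the FvCB literature.

photo:
  Vcmax25: 141.0        # umol CO2 m-2 s-1
  Jmax25: 186.0         # umol m-2 s-1
  Rd25: 1.5             # umol CO2 m-2 s-1
  gm25: 3.2             # umol m-2 s-1 Pa-1
  AbsPAR: 0.84
  Curv: 0.70
  f_spectral: 0.15
  Kc25: 404.9           # umol mol-1
  Ko25: 278.4           # mmol mol-1
  GammaStar25: 42.75    # umol mol-1
  O: 210.0              # mmol mol-1
  tauA_inc: 300.0       # s, induction
  tauA_dec: 1.0         # s, relaxation
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
  g0: 0.05              # mol m-2 s-1, nocturnal conductance
  g1: 11.0
  D0: 1.5               # kPa
  tauG_inc: 900.0       # s, opening
  tauG_dec: 450.0       # s, closing

energy:
  AbsShortwave: 0.50
  emissivity: 0.95
  k_heat: 280.0         # J m-2 K-1
  ksun: 0.465658        # W m-2 per umol m-2 s-1 = 1/(4.57*0.47)
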