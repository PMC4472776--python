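CHG:
  h_discharge:
  - 0.04610206604879821
  - 0.04995657146264144
  - 0.04484886747392177
  h_death:
  - 0.02046012527417091
  - 0.02096399648954913
  - 0.02020562466260895
  crbsi_h0: 0.00011663505943561516
  crbsi_slope: 1.0636864503573987e-05
  h_derm: 0.0023086817962298506
  h_newct: 0.02909319303906873
  crbsi_newct_frac: 1.0
nonCHG:
  h_discharge:
  - 0.052503872137899185
  - 0.04531302608506058
  - 0.04908793156602289
  h_death:
  - 0.01775925375481093
  - 0.02167343825604595
  - 0.026486162696594484
  crbsi_h0: 0.0006621290044504723
  crbsi_slope: 5.732020436417857e-05
  h_derm: 0.001018372215071298
  h_newct: 0.025521958727394295
  crbsi_newct_frac: 0.6418918918918919
bands:
- - 1
  - 5
- - 6
  - 15
- - 16
  - 30
horizon: 30
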