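# Reference 30-day ICU cohort occupancy profile (per 1,000 patients)
# to which the shipped synthetic matrices are calibrated.
CHG:
  ever_newct: 278.2
  ever_crbsi_noct: 0.0
  ever_crbsi_ct: 3.1
  ever_derm: 28.8
  ever_gauze: 28.8
  discharged: 604.1
  died: 263.7
  icu_days: 12.91
  days_to_discharge: 18.74
  days_to_death: 25.17
nonCHG:
  ever_newct: 251.6
  ever_crbsi_noct: 5.3
  ever_crbsi_ct: 9.5
  ever_derm: 12.7
  ever_gauze: 12.7
  discharged: 613.4
  died: 270.7
  icu_days: 12.72
  days_to_discharge: 18.43
  days_to_death: 25.28
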