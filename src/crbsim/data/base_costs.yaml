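c_icu_day: 1265.93
c_dressing_chg: 3.59
c_dressing_film: 0.18
c_dressing_gauze: 0.06
dressings_per_day: 1.0
c_ct_change: 94.97
c_crbsi_direct: 580.26
extra_los_crbsi: 9.33
c_derm_removal: 23.62
c_derm_dressings: 0.24
c_derm_insertion: 94.87
wtp: 41424.0
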