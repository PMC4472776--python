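"""Build the per-state daily cost tables for both dressing arms.

Each ICU day a patient occupies a health state, the cohort is charged
that state's daily cost (EUR 2013).  The CRBSI states carry the full
episode cost - direct treatment plus the cost of the attributable
extra ICU stay - as a lump on the diagnosis day.
"""

from crbsim import CostParameters, STATE_LABELS, build_state_costs, round_euro

params = CostParameters()  # base case
print(f"CRBSI episode cost: {params.c_crbsi_total:,.2f} EUR "
      f"(direct {params.c_crbsi_direct:,.2f} + "
      f"extra LOS {params.c_extra_los:,.2f})\n")

print(f"{'state':42s} {'CHG':>10s} {'non-CHG':>10s}")
chg = build_state_costs(params, "CHG")
ref = build_state_costs(params, "nonCHG")
for s in range(1, 9):
    print(f"{s}. {STATE_LABELS[s]:39s} {round_euro(chg[s]):>10,d} "
          f"{round_euro(ref[s]):>10,d}")

print("\nThe two arms differ only by the dressing applied each day; the")
print("gauze-and-tape state costs the same in both arms, and the")
print("absorbing states (discharge, death) cost nothing.")
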