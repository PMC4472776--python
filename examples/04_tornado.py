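"""One-way sensitivity of the between-arm cost difference (tornado).

Each parameter is pushed to the ends of its tested range with all
others at base case; entries are sorted by the spread they induce in
the mean cost difference.  Evaluation uses the analytic expected-cost
oracle, so the numbers carry no Monte Carlo noise.
"""

from crbsim import tornado
from crbsim.datasets import load_base_costs, load_reference_matrices
from crbsim.sensitivity import delta_cost_expected

params = load_base_costs()
m_chg = load_reference_matrices("CHG")
m_ref = load_reference_matrices("nonCHG")

base = delta_cost_expected(m_chg, m_ref, params)
print(f"base-case cost difference: {base:+.2f} EUR per patient\n")
print(f"{'parameter':26s} {'range':>16s} {'delta cost':>20s} {'spread':>8s}")
for e in tornado(params, m_chg, m_ref):
    print(f"{e.parameter:26s} [{e.low:7.2f},{e.high:7.2f}] "
          f"[{e.delta_cost_low:+8.2f},{e.delta_cost_high:+8.2f}] "
          f"{e.spread:8.2f}")

print("\nThe CRBSI-attributable extra ICU stay dominates: at one extra")
print("day the dressing costs more overall; at 26 extra days avoided")
print("infections save enough ICU time to make it cost-saving.")
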