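# crbsim

Cost-effectiveness microsimulation of antimicrobial (chlorhexidine
gluconate, CHG) catheter-securement dressings versus non-antimicrobial
transparent dressings for central vascular lines in intensive care.

Catheter-related bloodstream infections (CRBSIs) are rare but
expensive: each episode adds direct treatment costs and, above all,
extra ICU days.  A CHG gel dressing lowers the infection hazard at a
higher daily dressing price.  Whether that trade-off pays depends on
the full 30-day patient pathway — infections, catheter changes, dressing
intolerance, discharge and death all interact — which this package
models as an eight-state **non-homogeneous Markov chain** with one
matrix per ICU day, simulated patient by patient (microsimulation).

For health-economics and ICU-epidemiology researchers it provides, as
a Python library:

* the eight-state model: daily transition-matrix containers,
  validation, and per-state daily costing (EUR 2013);
* a vectorised Monte Carlo cohort simulator plus exact forward-product
  oracles (occupancy, cost, first-passage probabilities);
* estimation of daily matrices from longitudinal patient-day records;
* economic endpoints: incremental cost-effectiveness ratio
  (ICER = Δcost/Δeffect), incremental net monetary benefit
  (iNMB = Δeffect × WTP − Δcost), number needed to treat (NNT);
* one-way (tornado) and replicate-level probabilistic sensitivity
  analysis (PSA) with percentile confidence intervals and
  cost-effectiveness-plane export;
* a synthetic-data generator: interpretable daily hazards per arm,
  calibrated so simulated cohorts reproduce the published occupancy
  profile of the source randomized trial (≈3.1 vs ≈14.8 CRBSI patients
  per 1,000; ≈12.91 vs ≈12.72 mean ICU days).

The effect measure is CRBSIs avoided; the willingness to pay defaults
to €41,424, the mean cost of treating one infected reference-arm
patient.  See `docs/methods.md` for the model, assumptions and design
choices, and `examples/` for runnable walk-throughs of each capability.

## Worked example

```python
from crbsim import run_psa
from crbsim.datasets import load_base_costs, load_reference_matrices

params = load_base_costs()
psa = run_psa(
    load_reference_matrices("CHG"), load_reference_matrices("nonCHG"),
    params, n_reps=200, n_patients=1000, seed=1,
)
de, dc = psa.mean_delta_effect, psa.mean_delta_cost
print(f"CRBSIs avoided: {de * 1000:.2f} per 1,000 patients")
print(f"extra cost    : {dc:.2f} EUR per patient")
print(f"ICER          : {dc / de:,.0f} EUR per CRBSI avoided")
print(f"iNMB          : {de * params.wtp - dc:.2f} EUR per patient")
print(f"NNT           : {round(1 / de)} patients")
print(f"P(more effective): {psa.prob_more_effective:.3f}")
```

prints (examples/03, 200 replicates × 1,000 patients per arm):

```
CRBSIs avoided: 11.47 per 1,000 patients
extra cost    : 127.34 EUR per patient
ICER          : 11,106 EUR per CRBSI avoided
iNMB          : 347.59 EUR per patient
NNT           : 87 patients
P(more effective): 0.995
```

Read: the CHG dressing avoids ~11.5 infections per 1,000 patients for
~€127 more per patient; at €11.1k per infection avoided — far below
the ~€41k cost of treating one — the positive net monetary benefit
(≈€348/patient) says the dressing is cost-effective, and it was the
more effective strategy in 99.5% of replicates.

A thin CLI wraps the same pipeline
(`crbsim validate | estimate | simulate | analyze | psa | tornado |
calibrate | generate`); every run writes a manifest with the seed and
resolved parameters so results reproduce bit-identically.

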