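# Methods

## Model

`crbsim` follows an adult ICU patient day by day over a 30-day horizon
through eight mutually exclusive health states:

| id | state | role |
|----|-------|------|
| 1 | no CRBSI / no new catheter | baseline ICU day |
| 2 | no CRBSI / new catheter needed | catheter change or addition |
| 3 | CRBSI / no new catheter | infection day |
| 4 | CRBSI / new catheter | infection day with line replacement |
| 5 | contact dermatitis | dressing intolerance |
| 6 | gauze-and-tape dressing | permanent switch after dermatitis |
| 7 | discharge (alive) | absorbing |
| 8 | death in ICU | absorbing |

The chain is *non-homogeneous*: each day `t` has its own 8×8
row-stochastic matrix `P(t)`, and a cycle is exactly one ICU day.  Every
patient starts day 1 in state 1; the state on day `t+1` is a categorical
draw from the current state's row of `P(t)`.  The Markov assumption —
tomorrow depends only on today's state — is the model's central
simplification; day-specific matrices restore the empirically important
time dependence (notably the CRBSI hazard growing with catheterisation
time) without per-patient memory.

Two model conventions matter for every downstream number:

* **ICU days** count days spent in transient states 1–6; the day a
  patient first appears in an absorbing state is not an ICU day.
* **Days to discharge / death** are censored means: the first day in the
  absorbing state, over *all* patients, with patients never absorbed
  counted at the horizon (30).  Conditional-on-absorbed means are not
  mutually consistent with the ICU-day summary at this horizon, whereas
  the censored definitions satisfy the accounting identity
  `icu_days ≈ d_discharge + d_death − 31 + P(still in ICU)` up to one
  day of convention, which is how the three reference summaries relate.

## Costing

Each day in a transient state charges that state's daily cost (EUR
2013); absorbing states are free.  State costs are assembled from unit
costs: ICU day (€1,265.93), the arm's dressing (CHG €3.59, transparent
film €0.18, gauze €0.06; one dressing per day in the base case — the
published per-state totals are only consistent with one per day even
though observed change frequencies are lower, so the frequency is an
explicit, tornado-varied parameter), catheter change (€94.97, states 2
and 4), dermatitis episode (removal €23.62 + dressings €0.24 +
re-insertion €94.87, state 5), and the CRBSI episode: direct treatment
(€580.26) plus the cost of the CRBSI-attributable extra ICU stay
(9.33 days × ICU day cost in the base case, the average of the two
arms' model-based estimates of 8.55 and 10.1 days).

CRBSI states are assumed to last one day, so the full episode cost is a
lump charged on the diagnosis day.  With matrices in which CRBSI states
persisted longer, the lump would recur per occupied day — the analytic
cost oracle and the simulator deliberately share this per-day charging
rule so they agree exactly for *any* valid matrices.

Monetary quantities are kept at cent precision: the derived extra-LOS
cost is rounded to the cent before entering state costs (as composite
unit costs are quoted in accounting sources), and display rounding to
whole euros is half-away-from-zero.  All internal accumulation is
otherwise unrounded.

## Analytic oracles

Forward products of the daily matrices give exact expectations used
both as test oracles for the Monte Carlo engine and as the calibration
objective: the day-by-day state distribution `π(t+1) = π(t)·P(t)`, the
expected cost `Σ_t Σ_{s≤6} π_s(t)·c_s`, and first-passage ("ever
entered") probabilities obtained by making the target state — or a set
of states — absorbing and reading the trapped mass.  The set version
matters: the probability of ever experiencing a CRBSI is first passage
into the *union* {3, 4}; summing the two single-state passages would
double-count the rare patients who visit both.

## Economic endpoints

Effect is the per-patient probability of avoiding a CRBSI (reference
risk − intervention risk).  With `Δc` the between-arm mean cost and
`Δe` the effect difference:

* ICER = Δc / Δe (EUR per CRBSI avoided; undefined and flagged at Δe = 0),
* iNMB = Δe × WTP − Δc, with WTP defaulting to €41,424 — the mean cost
  of treating one infected patient in the reference arm,
* NNT = 1/Δe, rounded to the nearest integer (defined for Δe > 0).

The CRBSI-attributable extra ICU stay is estimated as the difference in
mean ICU days between patients ever in a CRBSI state and the rest, per
arm, with the base-case value the arithmetic mean of the two arms.

## Sensitivity analyses

**Probabilistic:** replicate-level Monte Carlo — 1,000 replicates of
1,000 patients per arm, each replicate seeded `base_seed + r` so the
whole analysis reproduces bit-identically from one seed.  95% intervals
are 2.5/97.5 percentiles of replicate statistics (the interval method is
a package choice; normal-approximation intervals differ negligibly at
1,000 replicates).  `prob_more_effective` is the fraction of
cost-effectiveness-plane points with Δe > 0.  No second-order parameter
distributions are drawn; the uncertainty quantified is sampling
variation of the cohorts.

**One-way (tornado):** one parameter at a time at the ends of its range,
everything else at base case.  The extra-LOS range (1–26 days) spans the
attributable-stay estimates reported in the ICU-infection literature;
ranges for the other parameters default to ±50% of base and are
overridable (they are package defaults, not published ranges).
Evaluation uses the analytic expected-cost oracle on the fixed matrices,
isolating the parameter effect from Monte Carlo noise (a
full-simulation mode exists behind a flag).  The cost difference is
affine in the extra-LOS parameter with slope −(difference in expected
CRBSI-days) × ICU-day cost, which the tests verify.

## Synthetic data generator and calibration

The source trial's patient database is not distributable, so the
package generates matrices with the structure the analysis assumes,
from interpretable daily hazards per arm:

* discharge and death: piecewise-constant over day bands (defaults
  1–5, 6–15, 16–30), giving enough freedom to match early-vs-late
  absorption and the day-count summaries;
* CRBSI: linear ramp `h0 + slope·(t−1)`, slope ≥ 0, encoding rising
  infection risk with line-days;
* dermatitis and new-catheter need: constant per day.

Implied dynamics: states 2–4 are one-day excursions returning to
baseline; dermatitis lasts one day and always moves to gauze-and-tape
(the dwell time is a modelling choice — the state diagram implies but
does not fix it); gauze-and-tape days follow the reference arm's
hazards, since such patients no longer wear the antimicrobial dressing.
The split of CRBSIs between states 3 and 4 is fixed at each arm's
reference ratio (intervention arm: all with new catheter).

`calibrate` fits the ten hazards per arm so the *analytic* summaries
match a target profile: per-1,000 patients ever entering each state,
mean ICU days, and censored days to discharge/death.  The objective is
a weighted sum of squared relative errors, minimised by derivative-free
Nelder–Mead in log-hazard space with seeded restarts (deterministic
given the seed; best-found parameters plus a warning if the budget is
exhausted).  Weights were fixed a priori: ICU days ×10 and CRBSI
frequency ×5, because those two summaries determine the economic
endpoints (cost and effect), while the day-to-absorption targets carry
the reference table's own ~0.1-day internal inconsistency.  The
reference arm is fitted first because its hazards also drive the
intervention arm's gauze-and-tape rows.

The shipped fixtures (`crbsim/data/`) are the calibrated hazards, the
matrices they generate, and the target profile.  Achieved fit: every
summary within 0.4% of target; ICU days and CRBSI frequency within
0.05%.  The fixtures are calibrated *emulations* of the original
(unpublished) trial matrices — cohort-level summaries are reproduced,
per-cell transition probabilities are not identifiable from them and no
per-cell agreement is claimed.

### What the generator does and does not emulate

It reproduces the competing-risk structure, the time-increasing
infection hazard, and the reference occupancy/cost profile.  It does
not model patient covariates (age, sex, severity scores), catheter-level
detail (the statistical unit is the patient), within-patient hazard
heterogeneity beyond state/day, or seasonal/centre effects.  Tests
passing on synthetic cohorts therefore establish the correctness of the
machinery and calibration-conditional reproduction of the published
results — not transportability of the clinical conclusions to settings
with different baseline infection rates.

## Matrix estimation from records

Given patient-day records, `p_ij(t) = n_ij(t)/n_i(t)` over patients
observed on consecutive days.  Preprocessing censors beyond day 30,
re-attributes a CRBSI recorded within two days after discharge to the
discharge day (deferring discharge by one day), and then drops any
later record that does not repeat the absorbing state.  A (day, state)
row with no occupants copies the nearest earlier day with data, else
the state's time-pooled row, else a unit self-loop — keeping matrices
stochastic without inventing transitions (the fallback is logged; how
the original analysis handled empty rows is not documented, so this is
a declared package choice).  The dermatitis row pools both arms'
counts; the intervention arm's gauze-and-tape rows are copied from the
reference arm.

## Numerical and scale choices

Row-stochasticity is enforced to 1e-9.  Cohort simulation is
vectorised inverse-CDF sampling (one uniform draw per patient-day); a
full 1,000 × 1,000 × 2-arm PSA takes a few seconds.  Tests run reduced
problem sizes where the check is statistical (50k–100k patients for
3-standard-error oracle agreement; the full study scale for the
endpoint reproduction tests), chosen so each check's Monte Carlo error
is well below the effect it verifies.  Statistical test tolerances are
standard-error based; where many cells are checked simultaneously the
bound is widened to keep the familywise false-alarm rate below 1%.

## Known limitations

* One reference cohort, one (French, low-incidence) setting; the
  calibrated matrices do not transport to other baseline rates.
* Effects are CRBSIs avoided only — no QALYs, no survival weighting,
  and no currency conversion beyond EUR 2013.
* The one-day CRBSI dwell assumption ties episode cost to diagnosis
  day; longer episodes would need a different cost-timing rule.
* Calibration matches cohort summaries, not individual transition
  cells; quantities dominated by unconstrained cells (e.g. day-30 tail
  behaviour of rare states) inherit generator assumptions rather than
  data.
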