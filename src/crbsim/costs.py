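"""Unit-cost parameters and the per-state daily cost construction.

Every day a patient occupies a transient state (1-6) the cohort is
charged that state's daily cost; absorbing states (discharge, death)
cost nothing.  The daily cost of a state is assembled from the unit
costs below (all in EUR 2013):

* states 1-6 carry the ICU day cost plus the arm's dressing cost;
* state 2 (and 4) add one catheter change;
* states 3 and 4 add the full CRBSI episode cost - the direct
  treatment cost plus the cost of the CRBSI-attributable extra ICU
  length of stay - charged as a lump on the (single) diagnosis day;
* state 5 adds the contact-dermatitis episode (catheter removal,
  replacement dressings, catheter re-insertion);
* state 6 swaps the transparent dressing for gauze and tape, which
  costs the same in both arms.

Monetary quantities are kept at cent precision: the derived extra-LOS
cost is rounded to the cent before entering the state costs, matching
how composite unit costs are quoted in accounting sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

from .states import ARM_CHG, ARMS, N_STATES


class CostValidationError(ValueError):
    """Raised when a cost parameter violates its constraints."""


@dataclass(frozen=True)
class CostParameters:
    """Unit-cost inputs of the analysis (EUR 2013).

    Defaults are the base case: a French ICU scenario with an observed
    low infection incidence.  ``wtp`` is the willingness to pay per
    CRBSI avoided, set to the mean cost of treating one patient with
    CRBSI in the reference (non-antimicrobial dressing) arm.
    """

    c_icu_day: float = 1265.93          # cost of one ICU day
    c_dressing_chg: float = 3.59        # CHG gel dressing, per dressing
    c_dressing_film: float = 0.18       # transparent film, per dressing
    c_dressing_gauze: float = 0.06      # gauze and tape, per dressing
    dressings_per_day: float = 1.0      # dressings applied per ICU day
    c_ct_change: float = 94.97          # catheter change (venous/arterial 50-50)
    c_crbsi_direct: float = 580.26      # direct treatment of one CRBSI episode
    extra_los_crbsi: float = 9.33       # CRBSI-attributable extra ICU days
    c_derm_removal: float = 23.62       # dermatitis: catheter removal
    c_derm_dressings: float = 0.24      # dermatitis: four gauze dressings
    c_derm_insertion: float = 94.87     # dermatitis: new catheter insertion
    wtp: float = 41424.0                # willingness to pay per CRBSI avoided

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise CostValidationError(f"{f.name} must be finite, got {value!r}")
            if value < 0:
                raise CostValidationError(f"{f.name} must be >= 0, got {value!r}")
        if self.dressings_per_day <= 0:
            raise CostValidationError("dressings_per_day must be > 0")

    def with_overrides(self, **kwargs: float) -> "CostParameters":
        return replace(self, **kwargs)

    @property
    def c_extra_los(self) -> float:
        """Cost of the CRBSI-attributable extra ICU stay, at cent precision."""
        return round(self.extra_los_crbsi * self.c_icu_day, 2)

    @property
    def c_crbsi_total(self) -> float:
        """Overall cost of one CRBSI episode (direct + extra LOS)."""
        return round(self.c_crbsi_direct + self.c_extra_los, 2)


@dataclass(frozen=True)
class StateCostTable:
    """Daily cost per health state for one arm (EUR per cycle occupied)."""

    arm: str
    costs: tuple[float, ...]  # index s - 1 holds c_s, s = 1..8

    def __post_init__(self) -> None:
        if len(self.costs) != N_STATES:
            raise CostValidationError(f"need {N_STATES} state costs, got {len(self.costs)}")

    def __getitem__(self, state: int) -> float:
        return self.costs[state - 1]

    def as_array(self):
        import numpy as np

        return np.asarray(self.costs, dtype=float)


def build_state_costs(params: CostParameters, arm: str) -> StateCostTable:
    """Assemble the per-state daily costs for one dressing arm.

    The arm only changes the dressing component of states 1-5: the CHG
    gel dressing in the intervention arm, the transparent film in the
    reference arm.  State 6 (gauze and tape) is identical in both arms.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    dressing = params.c_dressing_chg if arm == ARM_CHG else params.c_dressing_film
    c1 = params.c_icu_day + dressing * params.dressings_per_day
    c2 = c1 + params.c_ct_change
    c3 = c1 + params.c_crbsi_total
    c4 = c3 + params.c_ct_change
    c5 = c1 + (params.c_derm_removal + params.c_derm_dressings + params.c_derm_insertion)
    c6 = params.c_icu_day + params.c_dressing_gauze
    return StateCostTable(arm=arm, costs=(c1, c2, c3, c4, c5, c6, 0.0, 0.0))


def round_euro(x: float) -> int:
    """Round to whole euros, half away from zero (display convention).

    Values are first snapped to cent precision so that float noise a
    hair below .50 does not flip the rounded euro.
    """
    cents = round(x * 100)
    sign = 1 if cents >= 0 else -1
    return sign * ((abs(cents) + 50) // 100)
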