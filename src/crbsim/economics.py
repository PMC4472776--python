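"""Economic endpoints comparing the two dressing strategies.

The effect measure is the per-patient probability of avoiding a CRBSI
(reference-arm risk minus intervention-arm risk); costs are the mean
30-day accumulated cost per patient.  From those two differences:

* ICER  = delta_cost / delta_effect        (EUR per CRBSI avoided)
* iNMB  = delta_effect * WTP - delta_cost  (EUR per patient)
* NNT   = 1 / delta_effect                 (patients, nearest integer)

with WTP the willingness to pay per CRBSI avoided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .simulate import CohortResult

logger = logging.getLogger(__name__)


def extra_los(result: CohortResult) -> float:
    """CRBSI-attributable ICU stay prolongation in one cohort (days).

    Mean ICU days among patients who ever had a CRBSI minus the mean
    among those who never did.  Undefined (NaN, with a warning) if one
    of the subgroups is empty.
    """
    mask = result.crbsi_mask
    if mask.all() or not mask.any():
        logger.warning(
            "extra LOS undefined for arm %s: CRBSI subgroup of size %d out of %d",
            result.arm, int(mask.sum()), result.n_patients,
        )
        return math.nan
    return float(result.icu_days[mask].mean() - result.icu_days[~mask].mean())


@dataclass(frozen=True)
class CEResult:
    """Cost-effectiveness comparison of intervention vs reference arm."""

    delta_cost: float          # EUR per patient, intervention minus reference
    delta_effect: float        # CRBSIs avoided per patient
    icer: float                # EUR per CRBSI avoided (NaN if undefined)
    icer_defined: bool
    inmb: float                # EUR per patient
    nnt: int | None            # patients to treat to avoid one CRBSI
    wtp: float
    mean_cost: dict[str, float]            # per arm
    mean_cost_crbsi: dict[str, float]      # per arm, CRBSI subgroup
    mean_cost_no_crbsi: dict[str, float]   # per arm, CRBSI-free subgroup
    crbsi_risk: dict[str, float]           # per arm
    extra_los: dict[str, float]            # per arm (NaN if undefined)
    extra_los_pooled: float                # mean of the two arm estimates

    def to_text(self) -> str:
        lines = [
            "Cost-effectiveness report (intervention vs reference dressing)",
            f"  delta cost / patient     : {self.delta_cost:10.2f} EUR",
            f"  delta effect / patient   : {self.delta_effect * 1000:10.2f} CRBSIs avoided per 1,000",
            (
                f"  ICER                     : {self.icer:10.2f} EUR per CRBSI avoided"
                if self.icer_defined
                else "  ICER                     : undefined (zero effect difference)"
            ),
            f"  iNMB / patient           : {self.inmb:10.2f} EUR  (WTP = {self.wtp:,.2f})",
            f"  NNT                      : {self.nnt if self.nnt is not None else 'undefined'}",
            f"  extra ICU LOS (pooled)   : {self.extra_los_pooled:10.2f} days",
        ]
        for arm in self.mean_cost:
            lines.append(
                f"  [{arm}] mean cost {self.mean_cost[arm]:,.2f}; "
                f"CRBSI risk {self.crbsi_risk[arm] * 1000:.2f}/1,000; "
                f"cost with CRBSI {self.mean_cost_crbsi[arm]:,.2f}; "
                f"without {self.mean_cost_no_crbsi[arm]:,.2f}; "
                f"extra LOS {self.extra_los[arm]:.2f} d"
            )
        return "\n".join(lines)


def pooled_extra_los(chg_days: float, ref_days: float) -> float:
    """Base-case extra ICU LOS: arithmetic mean of the two arm estimates."""
    return (chg_days + ref_days) / 2.0


def _subgroup_mean(cost: np.ndarray, mask: np.ndarray) -> float:
    return float(cost[mask].mean()) if mask.any() else math.nan


def compare_arms(chg: CohortResult, ref: CohortResult, wtp: float) -> CEResult:
    """Compute all economic endpoints from two simulated cohorts.

    Both cohorts must have the same number of patients.  A zero effect
    difference leaves the ICER undefined (flagged) while the iNMB is
    still computed.
    """
    if chg.n_patients != ref.n_patients:
        raise ValueError(
            f"cohort sizes differ: {chg.n_patients} vs {ref.n_patients}"
        )
    delta_cost = chg.mean_cost - ref.mean_cost
    delta_effect = ref.crbsi_risk - chg.crbsi_risk
    icer_defined = delta_effect != 0.0
    icer = delta_cost / delta_effect if icer_defined else math.nan
    if not icer_defined:
        logger.warning("ICER undefined: both arms have equal CRBSI risk")
    inmb = delta_effect * wtp - delta_cost
    nnt = int(round(1.0 / delta_effect)) if delta_effect > 0 else None

    el = {chg.arm: extra_los(chg), ref.arm: extra_los(ref)}
    return CEResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        icer_defined=icer_defined,
        inmb=inmb,
        nnt=nnt,
        wtp=wtp,
        mean_cost={chg.arm: chg.mean_cost, ref.arm: ref.mean_cost},
        mean_cost_crbsi={
            chg.arm: _subgroup_mean(chg.cost, chg.crbsi_mask),
            ref.arm: _subgroup_mean(ref.cost, ref.crbsi_mask),
        },
        mean_cost_no_crbsi={
            chg.arm: _subgroup_mean(chg.cost, ~chg.crbsi_mask),
            ref.arm: _subgroup_mean(ref.cost, ~ref.crbsi_mask),
        },
        crbsi_risk={chg.arm: chg.crbsi_risk, ref.arm: ref.crbsi_risk},
        extra_los=el,
        extra_los_pooled=pooled_extra_los(el[chg.arm], el[ref.arm]),
    )
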