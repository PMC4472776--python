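"""One-way (tornado) and probabilistic sensitivity analyses.

The probabilistic sensitivity analysis is replicate-level Monte Carlo:
each of ``n_reps`` replicates simulates a fresh cohort per arm with
its own sub-seed and records the between-arm differences in effect and
cost.  The spread of those differences across replicates yields 95%
percentile confidence intervals and the probability that the
intervention is the more effective strategy (the fraction of
cost-effectiveness-plane points with a positive effect difference).

The tornado analysis re-evaluates the between-arm cost difference with
one cost parameter at a time pushed to the ends of its range, all
other inputs at base case.  By default it uses the analytic
expected-cost oracle on the fixed transition matrices, which isolates
the parameter's effect from Monte Carlo noise; a full-simulation mode
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import CostParameters, StateCostTable, build_state_costs
from .economics import compare_arms, extra_los
from .simulate import CohortResult, expected_cost, simulate_cohort, _require_valid
from .states import ARM_CHG, ARM_NONCHG, N_STATES, TransitionMatrixSet

#: tornado parameters; extra LOS spans the literature range of
#: CRBSI-attributable ICU prolongation (1-26 days), other ranges default
#: to +/-50% of base (set here as None and resolved against the base case)
DEFAULT_TORNADO_PARAMS = (
    "extra_los_crbsi",
    "c_dressing_chg",
    "dressings_per_day_chg",
    "dressings_per_day_nonchg",
    "c_icu_day",
)


@dataclass
class PSAResult:
    """Replicate-level Monte Carlo output for the two-arm comparison."""

    n_reps: int
    n_patients: int
    seed: int
    delta_effect: np.ndarray   # (n_reps,) per-patient CRBSI risk difference
    delta_cost: np.ndarray     # (n_reps,) per-patient cost difference (EUR)
    arm_stats: dict[str, pd.DataFrame]  # per arm, one row per replicate
    subgroup: dict[str, dict[str, float]] = field(default_factory=dict)

    # ----- summaries --------------------------------------------------------
    @staticmethod
    def _ci(x: np.ndarray) -> tuple[float, float]:
        return tuple(np.percentile(x, [2.5, 97.5]))

    @property
    def mean_delta_effect(self) -> float:
        return float(self.delta_effect.mean())

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def ci_delta_effect(self) -> tuple[float, float]:
        return self._ci(self.delta_effect)

    @property
    def ci_delta_cost(self) -> tuple[float, float]:
        return self._ci(self.delta_cost)

    @property
    def prob_more_effective(self) -> float:
        """Fraction of replicates in which the intervention avoids more CRBSIs."""
        return float((self.delta_effect > 0).mean())

    def mean_cost(self, arm: str) -> float:
        return float(self.arm_stats[arm]["mean_cost"].mean())

    def occupancy_table(self, arm: str) -> pd.DataFrame:
        """Mean and percentile 95% CI, per 1,000 patients, per state."""
        stats = self.arm_stats[arm]
        rows = []
        for s in range(1, N_STATES + 1):
            x = stats[f"ever_{s}"] * 1000.0 / self.n_patients
            lo, hi = self._ci(x.to_numpy())
            rows.append({"state": s, "mean": x.mean(), "lo95": lo, "hi95": hi})
        for name in ("icu_days", "days_to_discharge", "days_to_death"):
            x = stats[name]
            lo, hi = self._ci(x.to_numpy())
            rows.append({"state": name, "mean": x.mean(), "lo95": lo, "hi95": hi})
        return pd.DataFrame(rows)

    def ce_plane(self) -> pd.DataFrame:
        """Cost-effectiveness plane points, one per replicate."""
        return pd.DataFrame(
            {"delta_effect": self.delta_effect, "delta_cost": self.delta_cost}
        )

    def extra_los_estimate(self, arm: str) -> float:
        """Pooled-across-replicates CRBSI-attributable extra ICU stay (days)."""
        g = self.subgroup[arm]
        if g["n_crbsi"] == 0 or g["n_no_crbsi"] == 0:
            return float("nan")
        return g["icu_crbsi"] / g["n_crbsi"] - g["icu_no_crbsi"] / g["n_no_crbsi"]

    def mean_cost_subgroup(self, arm: str, crbsi: bool) -> float:
        g = self.subgroup[arm]
        n = g["n_crbsi"] if crbsi else g["n_no_crbsi"]
        tot = g["cost_crbsi"] if crbsi else g["cost_no_crbsi"]
        return tot / n if n else float("nan")


def _replicate_stats(res: CohortResult) -> dict[str, float]:
    row = {f"ever_{s}": res.ever_counts[s - 1] for s in range(1, N_STATES + 1)}
    row.update(
        mean_cost=res.mean_cost,
        icu_days=res.mean_icu_days,
        days_to_discharge=res.days_to_discharge,
        days_to_death=res.days_to_death,
        crbsi_risk=res.crbsi_risk,
        extra_los=extra_los(res) if 0 < res.n_crbsi_patients < res.n_patients else np.nan,
    )
    return row


def run_psa(
    m_chg: TransitionMatrixSet,
    m_ref: TransitionMatrixSet,
    params: CostParameters,
    n_reps: int = 1000,
    n_patients: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Replicate-level PSA of intervention vs reference arm.

    Replicate ``r`` draws both arms from a generator seeded
    ``seed + r``, so the whole analysis is reproducible from one seed
    and replicates are mutually independent.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to form confidence intervals")
    _require_valid(m_chg)
    _require_valid(m_ref)
    costs = {
        ARM_CHG: build_state_costs(params, ARM_CHG),
        ARM_NONCHG: build_state_costs(params, ARM_NONCHG),
    }
    arms = {ARM_CHG: m_chg, ARM_NONCHG: m_ref}

    delta_effect = np.empty(n_reps)
    delta_cost = np.empty(n_reps)
    rows: dict[str, list[dict]] = {a: [] for a in arms}
    subgroup = {
        a: dict(icu_crbsi=0.0, icu_no_crbsi=0.0, cost_crbsi=0.0,
                cost_no_crbsi=0.0, n_crbsi=0, n_no_crbsi=0)
        for a in arms
    }

    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        results = {}
        for arm in (ARM_CHG, ARM_NONCHG):
            res = simulate_cohort(
                arms[arm], costs[arm], n_patients, rng=rng, validate=False
            )
            results[arm] = res
            rows[arm].append(_replicate_stats(res))
            g = subgroup[arm]
            mask = res.crbsi_mask
            g["icu_crbsi"] += float(res.icu_days[mask].sum())
            g["icu_no_crbsi"] += float(res.icu_days[~mask].sum())
            g["cost_crbsi"] += float(res.cost[mask].sum())
            g["cost_no_crbsi"] += float(res.cost[~mask].sum())
            g["n_crbsi"] += int(mask.sum())
            g["n_no_crbsi"] += int((~mask).sum())
        delta_effect[r] = (
            results[ARM_NONCHG].crbsi_risk - results[ARM_CHG].crbsi_risk
        )
        delta_cost[r] = results[ARM_CHG].mean_cost - results[ARM_NONCHG].mean_cost

    return PSAResult(
        n_reps=n_reps,
        n_patients=n_patients,
        seed=seed,
        delta_effect=delta_effect,
        delta_cost=delta_cost,
        arm_stats={a: pd.DataFrame(rows[a]) for a in arms},
        subgroup=subgroup,
    )


# --------------------------------------------------------------------------
# tornado
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    delta_cost_low: float
    delta_cost_high: float

    @property
    def spread(self) -> float:
        return abs(self.delta_cost_high - self.delta_cost_low)


def _arm_costs(params: CostParameters, parameter: str, value: float
               ) -> dict[str, StateCostTable]:
    """State costs with one (possibly arm-specific) parameter overridden."""
    if parameter == "dressings_per_day_chg":
        return {
            ARM_CHG: build_state_costs(
                params.with_overrides(dressings_per_day=value), ARM_CHG
            ),
            ARM_NONCHG: build_state_costs(params, ARM_NONCHG),
        }
    if parameter == "dressings_per_day_nonchg":
        return {
            ARM_CHG: build_state_costs(params, ARM_CHG),
            ARM_NONCHG: build_state_costs(
                params.with_overrides(dressings_per_day=value), ARM_NONCHG
            ),
        }
    varied = params.with_overrides(**{parameter: value})
    return {
        ARM_CHG: build_state_costs(varied, ARM_CHG),
        ARM_NONCHG: build_state_costs(varied, ARM_NONCHG),
    }


def delta_cost_expected(
    m_chg: TransitionMatrixSet,
    m_ref: TransitionMatrixSet,
    params: CostParameters,
    parameter: str | None = None,
    value: float | None = None,
) -> float:
    """Deterministic between-arm cost difference via the analytic oracle."""
    if parameter is None:
        costs = _arm_costs(params, "c_icu_day", params.c_icu_day)
    else:
        costs = _arm_costs(params, parameter, value)
    return expected_cost(m_chg, costs[ARM_CHG], validate=False) - expected_cost(
        m_ref, costs[ARM_NONCHG], validate=False
    )


def default_tornado_ranges(params: CostParameters) -> dict[str, tuple[float, float]]:
    """Tested ranges: extra LOS 1-26 days; other parameters +/-50% of base."""
    return {
        "extra_los_crbsi": (1.0, 26.0),
        "c_dressing_chg": (0.5 * params.c_dressing_chg, 1.5 * params.c_dressing_chg),
        "dressings_per_day_chg": (
            0.5 * params.dressings_per_day, 1.5 * params.dressings_per_day
        ),
        "dressings_per_day_nonchg": (
            0.5 * params.dressings_per_day, 1.5 * params.dressings_per_day
        ),
        "c_icu_day": (0.5 * params.c_icu_day, 1.5 * params.c_icu_day),
    }


def tornado(
    base: CostParameters,
    m_chg: TransitionMatrixSet,
    m_ref: TransitionMatrixSet,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    use_simulation: bool = False,
    n_reps: int = 200,
    n_patients: int = 1000,
    seed: int = 0,
) -> list[TornadoEntry]:
    """One-way sensitivity of the between-arm cost difference.

    Each entry evaluates the cost difference with one parameter at the
    low and high end of its range (everything else at base case) and
    is sorted descending by spread.
    """
    if param_ranges is None:
        param_ranges = default_tornado_ranges(base)
    if not param_ranges:
        raise ValueError("param_ranges must contain at least one parameter")
    _require_valid(m_chg)
    _require_valid(m_ref)

    def evaluate(parameter: str, value: float) -> float:
        if not use_simulation:
            return delta_cost_expected(m_chg, m_ref, base, parameter, value)
        costs = _arm_costs(base, parameter, value)
        diffs = np.empty(n_reps)
        for r in range(n_reps):
            rng = np.random.default_rng(seed + r)
            chg = simulate_cohort(m_chg, costs[ARM_CHG], n_patients, rng=rng,
                                  validate=False)
            ref = simulate_cohort(m_ref, costs[ARM_NONCHG], n_patients, rng=rng,
                                  validate=False)
            diffs[r] = chg.mean_cost - ref.mean_cost
        return float(diffs.mean())

    entries = [
        TornadoEntry(
            parameter=name,
            low=lo,
            high=hi,
            delta_cost_low=evaluate(name, lo),
            delta_cost_high=evaluate(name, hi),
        )
        for name, (lo, hi) in param_ranges.items()
    ]
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_dataframe(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "delta_cost_low": e.delta_cost_low,
                "delta_cost_high": e.delta_cost_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    )
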