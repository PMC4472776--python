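"""Monte Carlo microsimulation of patient trajectories and its analytic twin.

Each simulated patient is an independent realisation of the
non-homogeneous Markov chain: starting day 1 in state 1, the state on
day ``t + 1`` is drawn from the current state's row of day ``t``'s
matrix.  Costs accumulate per day occupied in a transient state.

The module also provides closed-form expectations (forward products of
the daily matrices) used as deterministic oracles for the Monte Carlo
engine and as the objective of the synthetic-data calibration:

* :func:`expected_occupancy` - the exact day-by-day state distribution;
* :func:`expected_cost` - the exact mean cost per patient;
* :func:`ever_entry_probability` - the exact probability of ever
  visiting a given state within the horizon (first-passage mass
  through a modified chain in which that state is made absorbing).

Day-count conventions (used consistently throughout):

* ``icu_days`` counts days spent in transient states 1-6; the day a
  patient first appears in an absorbing state is not an ICU day.
* ``days_to_discharge`` / ``days_to_death`` are the mean first-entry
  day of the absorbing state over *all* patients, with patients who
  never enter it counted at the horizon (censored means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costs import StateCostTable
from .states import (
    CRBSI_STATES,
    MatrixValidationError,
    N_STATES,
    TransitionMatrixSet,
    validate_matrices,
)


@dataclass
class CohortResult:
    """One simulated cohort of a single arm.

    Attributes
    ----------
    trajectories:
        ``(n_patients, horizon)`` int8 array of 1-based state ids;
        column ``t - 1`` is the state occupied on day ``t``.
    cost:
        per-patient accumulated cost over the horizon (EUR).
    """

    arm: str
    n_patients: int
    horizon: int
    trajectories: np.ndarray
    cost: np.ndarray

    # derived per-patient arrays, filled in __post_init__
    icu_days: np.ndarray = None
    ever: np.ndarray = None  # (n_patients, 8) bool, ever occupied state s

    def __post_init__(self) -> None:
        traj = self.trajectories
        self.ever = np.stack(
            [(traj == s).any(axis=1) for s in range(1, N_STATES + 1)], axis=1
        )
        self.icu_days = (traj <= 6).sum(axis=1)

    # ----- scalar summaries -------------------------------------------------
    @property
    def ever_counts(self) -> np.ndarray:
        """Patients ever entering each state (length-8, index s - 1)."""
        return self.ever.sum(axis=0)

    @property
    def crbsi_mask(self) -> np.ndarray:
        return self.ever[:, CRBSI_STATES[0] - 1] | self.ever[:, CRBSI_STATES[1] - 1]

    @property
    def n_crbsi_patients(self) -> int:
        return int(self.crbsi_mask.sum())

    @property
    def crbsi_risk(self) -> float:
        """Per-patient probability of ever experiencing a CRBSI."""
        return self.n_crbsi_patients / self.n_patients

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_icu_days(self) -> float:
        return float(self.icu_days.mean())

    def first_entry_day(self, state: int) -> np.ndarray:
        """Per-patient first day in ``state``, censored at the horizon."""
        hit = self.trajectories == state
        any_hit = hit.any(axis=1)
        first = np.where(any_hit, hit.argmax(axis=1) + 1, self.horizon)
        return first

    @property
    def days_to_discharge(self) -> float:
        return float(self.first_entry_day(7).mean())

    @property
    def days_to_death(self) -> float:
        return float(self.first_entry_day(8).mean())

    def occupancy_per_1000(self) -> dict[int, float]:
        """Patients per 1,000 ever entering each state."""
        return {
            s: 1000.0 * self.ever_counts[s - 1] / self.n_patients
            for s in range(1, N_STATES + 1)
        }


def _require_valid(matrices: TransitionMatrixSet) -> None:
    report = validate_matrices(matrices)
    if not report.ok:
        raise MatrixValidationError(
            "refusing to simulate with invalid matrices: "
            + "; ".join(report.violations[:5])
        )


def simulate_cohort(
    matrices: TransitionMatrixSet,
    costs: StateCostTable,
    n_patients: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    validate: bool = True,
) -> CohortResult:
    """Simulate ``n_patients`` independent 30-day trajectories of one arm.

    Every patient starts day 1 in state 1.  Pass either an explicit
    ``seed`` or an existing ``rng`` (one of the two is required so runs
    are reproducible by construction); the same seed yields a
    bit-identical :class:`CohortResult`.
    """
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed or an rng; implicit seeding is not allowed")
        rng = np.random.default_rng(seed)
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if validate:
        _require_valid(matrices)

    horizon = matrices.horizon
    # cumulative rows per day for inverse-CDF draws
    cum = np.cumsum(matrices.P, axis=2)
    c = costs.as_array()

    traj = np.empty((n_patients, horizon), dtype=np.int8)
    states = np.zeros(n_patients, dtype=np.intp)  # 0-based state index
    traj[:, 0] = 1
    cost = np.full(n_patients, c[0], dtype=float)

    for t in range(1, horizon):
        u = rng.random(n_patients)
        rows = cum[t - 1, states, :]  # (n, 8) cumulative probabilities
        states = (u[:, None] > rows).sum(axis=1)
        traj[:, t] = states + 1
        cost += np.where(states <= 5, c[states], 0.0)

    return CohortResult(
        arm=matrices.arm,
        n_patients=n_patients,
        horizon=horizon,
        trajectories=traj,
        cost=cost,
    )


# --------------------------------------------------------------------------
# analytic oracles
# --------------------------------------------------------------------------

def expected_occupancy(
    matrices: TransitionMatrixSet, horizon: int | None = None, validate: bool = True
) -> np.ndarray:
    """Exact state distribution per day: ``pi[t - 1, s - 1] = P(state(t) = s)``.

    ``pi(1)`` is a point mass on state 1 and ``pi(t + 1) = pi(t) P(t)``.
    Returns an ``(horizon, 8)`` array whose rows each sum to 1.
    """
    if validate:
        _require_valid(matrices)
    horizon = matrices.horizon if horizon is None else horizon
    pi = np.zeros((horizon, N_STATES))
    pi[0, 0] = 1.0
    for t in range(1, horizon):
        pi[t] = pi[t - 1] @ matrices.P[t - 1]
    return pi


def expected_cost(
    matrices: TransitionMatrixSet,
    costs: StateCostTable,
    horizon: int | None = None,
    validate: bool = True,
) -> float:
    """Exact mean cost per patient: sum_t sum_{s<=6} pi_s(t) c_s."""
    pi = expected_occupancy(matrices, horizon, validate=validate)
    c = costs.as_array()
    return float((pi[:, :6] * c[:6]).sum())


def expected_icu_days(matrices: TransitionMatrixSet, validate: bool = True) -> float:
    """Exact mean number of days spent in transient states 1-6."""
    pi = expected_occupancy(matrices, validate=validate)
    return float(pi[:, :6].sum())


def ever_entry_probability(
    matrices: TransitionMatrixSet,
    states: int | tuple[int, ...],
    validate: bool = True,
) -> float:
    """Exact probability of visiting ``states`` at least once within the horizon.

    ``states`` may be a single state id or a set of ids, in which case
    the probability refers to the first entry into any of them (so
    patients visiting several of the states are counted once).
    Computed by making the states absorbing and reading the trapped
    mass after the final cycle (first-passage probability).
    """
    return float(_ever_entry_series(matrices, states, validate=validate)[-1])


def _ever_entry_series(
    matrices: TransitionMatrixSet,
    states: int | tuple[int, ...],
    validate: bool = True,
) -> np.ndarray:
    """``F[t - 1] = P(first entry into states <= day t)`` for t = 1..horizon."""
    if validate:
        _require_valid(matrices)
    idx = np.atleast_1d(np.asarray(states, dtype=int)) - 1
    horizon = matrices.horizon
    F = np.zeros(horizon)
    pi = np.zeros(N_STATES)
    pi[0] = 1.0
    if 0 in idx:
        F[:] = 1.0  # everyone starts in state 1
        return F
    trapped = 0.0
    for t in range(1, horizon):
        P = matrices.P[t - 1]
        pi = pi @ P
        trapped += pi[idx].sum()
        pi[idx] = 0.0
        F[t] = trapped
    return F


def expected_first_entry_day(
    matrices: TransitionMatrixSet, state: int, validate: bool = True
) -> float:
    """Exact mean first-entry day of ``state``, censored at the horizon.

    Matches :meth:`CohortResult.first_entry_day` in expectation:
    ``E[min(T_state, horizon)]`` with ``T`` the 1-based first day in
    the state (patients never entering count at the horizon).
    """
    F = _ever_entry_series(matrices, state, validate=validate)
    horizon = matrices.horizon
    # E[T ^ H] = H - sum_{t=1..H-1} F(t)
    return float(horizon - F[:-1].sum())
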