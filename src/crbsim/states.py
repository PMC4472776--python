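"""Health-state space and daily transition-matrix containers.

The model follows an ICU patient over a 30-day horizon through eight
mutually exclusive health states, one state per day (one Markov cycle
= one ICU day).  The chain is non-homogeneous: each day ``t`` has its
own 8x8 row-stochastic matrix ``P(t)`` governing the move from day
``t`` to day ``t + 1``.

States
------
1. no CRBSI / no new catheter (baseline ICU day)
2. no CRBSI / new catheter needed
3. CRBSI / no new catheter
4. CRBSI / new catheter needed
5. contact dermatitis
6. gauze-and-tape dressing (after dermatitis)
7. discharged alive from the ICU (absorbing)
8. death in the ICU (absorbing)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_STATES = 8
HORIZON = 30

#: 1-based state id -> label
STATE_LABELS: dict[int, str] = {
    1: "no CRBSI / no new CT",
    2: "no CRBSI / new CT",
    3: "CRBSI / no new CT",
    4: "CRBSI / new CT",
    5: "contact dermatitis",
    6: "gauze-and-tape dressing",
    7: "discharge",
    8: "death",
}

ABSORBING_STATES = (7, 8)
TRANSIENT_STATES = (1, 2, 3, 4, 5, 6)
CRBSI_STATES = (3, 4)

ARM_CHG = "CHG"
ARM_NONCHG = "nonCHG"
ARMS = (ARM_CHG, ARM_NONCHG)

ROW_SUM_TOL = 1e-9


class MatrixValidationError(ValueError):
    """Raised when a transition-matrix set violates its invariants."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_matrices`.

    ``violations`` lists human-readable messages, each tagged with the
    offending (day, state) row where applicable.
    """

    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


@dataclass
class TransitionMatrixSet:
    """Per-arm stack of daily transition matrices.

    Parameters
    ----------
    arm:
        ``"CHG"`` or ``"nonCHG"``.
    P:
        Array of shape ``(horizon, 8, 8)``; ``P[t - 1, i - 1, j - 1]``
        is the probability of moving from state ``i`` on day ``t`` to
        state ``j`` on day ``t + 1`` (1-based days and states).
    """

    arm: str
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 3 or self.P.shape[1:] != (N_STATES, N_STATES):
            raise MatrixValidationError(
                f"expected shape (horizon, {N_STATES}, {N_STATES}), got {self.P.shape}"
            )
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")

    @property
    def horizon(self) -> int:
        return self.P.shape[0]

    def day(self, t: int) -> np.ndarray:
        """Matrix governing the day ``t`` -> ``t + 1`` move (1-based)."""
        if not 1 <= t <= self.horizon:
            raise IndexError(f"day {t} outside 1..{self.horizon}")
        return self.P[t - 1]

    def validate(self) -> ValidationReport:
        return validate_matrices(self)


def validate_matrices(matrices: TransitionMatrixSet) -> ValidationReport:
    """Check row-stochasticity, probability bounds and absorbing rows.

    Returns a :class:`ValidationReport` whose ``violations`` name every
    offending (day, state) row; structural problems (wrong shape) raise
    :class:`MatrixValidationError` from the container itself.
    """
    P = matrices.P
    violations: list[str] = []

    bad_bounds = (P < -ROW_SUM_TOL) | (P > 1 + ROW_SUM_TOL)
    for t, i, j in zip(*np.nonzero(bad_bounds)):
        violations.append(
            f"day {t + 1}, state {i + 1}: entry p({i + 1}->{j + 1}) = "
            f"{P[t, i, j]:.6g} outside [0, 1]"
        )

    row_sums = P.sum(axis=2)
    bad_rows = np.abs(row_sums - 1.0) > ROW_SUM_TOL
    for t, i in zip(*np.nonzero(bad_rows)):
        violations.append(
            f"day {t + 1}, state {i + 1}: row sums to {row_sums[t, i]:.12g}"
        )

    for s in ABSORBING_STATES:
        rows = P[:, s - 1, :]
        expected = np.zeros(N_STATES)
        expected[s - 1] = 1.0
        not_self = np.abs(rows - expected).max(axis=1) > ROW_SUM_TOL
        for t in np.nonzero(not_self)[0]:
            violations.append(
                f"day {t + 1}, state {s}: absorbing row is not a unit self-loop"
            )

    return ValidationReport(ok=not violations, violations=violations)


def identity_matrices(arm: str = ARM_CHG, horizon: int = HORIZON) -> TransitionMatrixSet:
    """All-identity dynamics: every state (absorbing everywhere) holds itself."""
    P = np.broadcast_to(np.eye(N_STATES), (horizon, N_STATES, N_STATES)).copy()
    return TransitionMatrixSet(arm=arm, P=P)
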