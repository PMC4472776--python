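"""Shared builders for test matrices and cohorts."""

from __future__ import annotations

import numpy as np

from crbsim.states import ABSORBING_STATES, N_STATES, TransitionMatrixSet


def deterministic_chain(moves: dict[int, int], arm: str = "CHG",
                        horizon: int = 30) -> TransitionMatrixSet:
    """Every day, state i moves to moves[i] with probability 1 (default: stay)."""
    P = np.zeros((horizon, N_STATES, N_STATES))
    for i in range(1, N_STATES + 1):
        j = moves.get(i, i)
        P[:, i - 1, j - 1] = 1.0
    for s in ABSORBING_STATES:
        P[:, s - 1, :] = 0.0
        P[:, s - 1, s - 1] = 1.0
    return TransitionMatrixSet(arm=arm, P=P)


def random_matrix_set(seed: int, arm: str = "CHG", horizon: int = 30,
                      stickiness: float = 6.0) -> TransitionMatrixSet:
    """Random valid daily matrices with self-transition bias.

    ``stickiness`` weights the diagonal so trajectories do not mix to
    uniformity instantly; absorbing rows are forced to self-loops.
    """
    rng = np.random.default_rng(seed)
    P = rng.random((horizon, N_STATES, N_STATES))
    for i in range(N_STATES):
        P[:, i, i] += stickiness
    P /= P.sum(axis=2, keepdims=True)
    for s in ABSORBING_STATES:
        P[:, s - 1, :] = 0.0
        P[:, s - 1, s - 1] = 1.0
    return TransitionMatrixSet(arm=arm, P=P)
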