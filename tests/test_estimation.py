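"""Record preprocessing rules and count-ratio matrix estimation."""

import numpy as np
import pandas as pd
import pytest

from helpers import deterministic_chain

from crbsim.estimation import (
    RecordError,
    estimate_matrices,
    preprocess_records,
)
from crbsim.states import ARM_CHG, ARM_NONCHG, validate_matrices
from crbsim.synthetic import generate_records


def rec(pid, arm, day, state):
    return {"patient_id": pid, "arm": arm, "day": day, "state": state}


def frame(*rows):
    return pd.DataFrame(list(rows))


# ----- preprocessing ---------------------------------------------------------

def test_days_beyond_horizon_are_censored():
    df = frame(*[rec(1, ARM_CHG, d, 1) for d in range(1, 36)])
    out = preprocess_records(df, horizon=30)
    assert out["day"].max() == 30
    assert len(out) == 30


def test_crbsi_within_two_days_of_discharge_is_reattributed():
    df = frame(
        *[rec(1, ARM_CHG, d, 1) for d in range(1, 10)],
        rec(1, ARM_CHG, 10, 7),
        rec(1, ARM_CHG, 11, 3),
    )
    out = preprocess_records(df)
    day10 = out[(out.patient_id == 1) & (out.day == 10)]["state"].item()
    day11 = out[(out.patient_id == 1) & (out.day == 11)]["state"].item()
    assert day10 == 3  # infection attributed to the discharge day
    assert day11 == 7  # discharge deferred by one day


def test_crbsi_two_days_after_discharge_still_reattributed():
    df = frame(
        rec(1, ARM_CHG, 1, 1),
        rec(1, ARM_CHG, 2, 7),
        rec(1, ARM_CHG, 4, 4),
    )
    out = preprocess_records(df)
    assert out[(out.day == 2)]["state"].item() == 4
    assert out[(out.day == 3)]["state"].item() == 7


def test_crbsi_three_days_after_discharge_not_reattributed():
    df = frame(
        rec(1, ARM_CHG, 1, 1),
        rec(1, ARM_CHG, 2, 7),
        rec(1, ARM_CHG, 5, 3),  # outside the two-day window
    )
    out = preprocess_records(df)
    assert out[(out.day == 2)]["state"].item() == 7
    # the stray post-discharge infection is dropped, permanence restored
    assert 3 not in out["state"].values


def test_post_absorption_repeats_are_kept():
    df = frame(
        rec(1, ARM_CHG, 1, 1),
        rec(1, ARM_CHG, 2, 8),
        rec(1, ARM_CHG, 3, 8),
    )
    out = preprocess_records(df)
    assert len(out) == 3


@pytest.mark.parametrize(
    "rows,msg",
    [
        ([rec(1, ARM_CHG, 1, 9)], "state"),
        ([rec(1, ARM_CHG, 0, 1)], "day"),
        ([rec(1, ARM_CHG, 1, 1), rec(1, ARM_CHG, 1, 2)], "duplicate"),
        ([rec(1, "other", 1, 1)], "arm"),
    ],
)
def test_malformed_records_rejected(rows, msg):
    with pytest.raises(RecordError, match=msg):
        preprocess_records(frame(*rows))


# ----- estimation ------------------------------------------------------------

def test_direct_count_ratio():
    df = frame(
        rec(1, ARM_CHG, 1, 1), rec(1, ARM_CHG, 2, 1),
        rec(2, ARM_CHG, 1, 1), rec(2, ARM_CHG, 2, 7),
    )
    m = estimate_matrices(df, ARM_CHG)
    assert m.P[0, 0, 0] == pytest.approx(0.5)
    assert m.P[0, 0, 6] == pytest.approx(0.5)
    assert validate_matrices(m).ok


def naive_tally(df, horizon=30):
    """Independent brute-force transition tally (dict-based)."""
    counts = {}
    for _, g in df.sort_values(["patient_id", "day"]).groupby("patient_id"):
        rows = list(g.itertuples())
        for a, b in zip(rows, rows[1:]):
            if b.day == a.day + 1 and a.day < horizon:
                counts[(a.day, a.state, b.state)] = counts.get(
                    (a.day, a.state, b.state), 0
                ) + 1
    return counts


def test_toy_cohort_matches_hand_tally():
    df = frame(
        # five hand-written non-CHG trajectories
        rec(1, ARM_NONCHG, 1, 1), rec(1, ARM_NONCHG, 2, 1), rec(1, ARM_NONCHG, 3, 7),
        rec(2, ARM_NONCHG, 1, 1), rec(2, ARM_NONCHG, 2, 2), rec(2, ARM_NONCHG, 3, 1),
        rec(3, ARM_NONCHG, 1, 1), rec(3, ARM_NONCHG, 2, 3), rec(3, ARM_NONCHG, 3, 8),
        rec(4, ARM_NONCHG, 1, 1), rec(4, ARM_NONCHG, 2, 1), rec(4, ARM_NONCHG, 3, 1),
        rec(5, ARM_NONCHG, 1, 1), rec(5, ARM_NONCHG, 2, 5), rec(5, ARM_NONCHG, 3, 6),
        rec(5, ARM_NONCHG, 4, 7),
    )
    m = estimate_matrices(df, ARM_NONCHG)
    tally = naive_tally(df)
    for day in (1, 2, 3):
        for i in range(1, 7):
            n_i = sum(v for (d, a, _), v in tally.items() if d == day and a == i)
            if n_i == 0:
                continue
            for j in range(1, 9):
                expected = tally.get((day, i, j), 0) / n_i
                assert m.P[day - 1, i - 1, j - 1] == pytest.approx(expected), (
                    day, i, j
                )
    assert validate_matrices(m).ok


def test_dermatitis_row_is_pooled_across_arms():
    # CHG: 5 -> 6; nonCHG: 5 -> 7 on day 1, one patient each -> pooled 50/50
    df = frame(
        rec(1, ARM_CHG, 1, 5), rec(1, ARM_CHG, 2, 6),
        rec(2, ARM_NONCHG, 1, 5), rec(2, ARM_NONCHG, 2, 7),
        # some state-1 mass so other rows are not empty
        rec(3, ARM_CHG, 1, 1), rec(3, ARM_CHG, 2, 1),
        rec(4, ARM_NONCHG, 1, 1), rec(4, ARM_NONCHG, 2, 1),
    )
    for arm in (ARM_CHG, ARM_NONCHG):
        m = estimate_matrices(df, arm)
        assert m.P[0, 4, 5] == pytest.approx(0.5)
        assert m.P[0, 4, 6] == pytest.approx(0.5)


def test_gauze_rows_copied_from_reference_arm():
    df = frame(
        rec(1, ARM_CHG, 1, 6), rec(1, ARM_CHG, 2, 6),       # CHG: 6 -> 6
        rec(2, ARM_NONCHG, 1, 6), rec(2, ARM_NONCHG, 2, 7),  # nonCHG: 6 -> 7
    )
    chg = estimate_matrices(df, ARM_CHG)
    ref = estimate_matrices(df, ARM_NONCHG)
    # the intervention arm's own 6 -> 6 transition is ignored in favour of
    # the reference arm's row
    assert chg.P[0, 5, 6] == 1.0
    assert np.array_equal(chg.P[:, 5, :], ref.P[:, 5, :])


def test_empty_row_fallback_copies_nearest_earlier_day():
    df = frame(
        rec(1, ARM_CHG, 1, 1), rec(1, ARM_CHG, 2, 2), rec(1, ARM_CHG, 3, 1),
        rec(1, ARM_CHG, 4, 1), rec(1, ARM_CHG, 5, 1),
    )
    m = estimate_matrices(df, ARM_CHG)
    # state 2 only observed on day 2 (2 -> 1); later days copy that row
    assert m.P[1, 1, 0] == 1.0
    assert m.P[10, 1, 0] == 1.0
    # states never observed fall back to self-loops
    assert m.P[0, 4, 4] == 1.0
    assert validate_matrices(m).ok


def test_round_trip_recovers_generating_matrices(ref_matrices):
    """Estimated p_ij(t) within 3 binomial SE of truth for well-filled cells."""
    n = 100_000
    frames = [
        generate_records(ref_matrices[arm], n=n, seed=s)
        for arm, s in ((ARM_CHG, 21), (ARM_NONCHG, 22))
    ]
    frames[1]["patient_id"] += n  # disjoint patient ids
    records = pd.concat(frames, ignore_index=True)
    records = preprocess_records(records)
    for arm in (ARM_CHG, ARM_NONCHG):
        est = estimate_matrices(records, arm)
        assert validate_matrices(est).ok
        truth = ref_matrices[arm]
        own = records[records.arm == arm]
        for t in (1, 5, 10, 20):
            nxt = set(own[own.day == t + 1].patient_id)
            # rows 1-4 are estimated from the arm's own transitions; the
            # pooled/copied rows 5-6 have dedicated tests above
            for i in range(1, 5):
                # occupants with a recorded next day
                ids = own[(own.day == t) & (own.state == i)].patient_id
                n_i = int(ids.isin(nxt).sum())
                if n_i < 50:
                    continue
                p = truth.P[t - 1, i - 1, :]
                se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / n_i)
                err = np.abs(est.P[t - 1, i - 1, :] - p)
                # ~256 cells are checked at once; 4 SE keeps the
                # familywise false-alarm rate below 1%
                assert (err <= 4 * se + 1e-9).all(), (arm, t, i)
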