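"""Estimate daily transition matrices from longitudinal patient-day records.

Records are one row per patient-day (``patient_id, arm, day, state``).
Estimation is the straightforward occupancy-conditional count ratio

    p_ij(t) = n_ij(t) / n_i(t)

where ``n_i(t)`` counts patients observed in state ``i`` on day ``t``
with day ``t + 1`` also recorded, and ``n_ij(t)`` those among them who
moved to ``j``.

Preprocessing applies the analysis conventions before counting:

* observations beyond the 30-day horizon are censored;
* a CRBSI recorded within two days after a discharge is attributed to
  the ICU stay: the infection is moved onto the discharge day and the
  discharge is deferred to the next day;
* absorbing permanence is then re-established - any record after the
  first discharge/death that does not simply repeat the absorbing
  state is dropped.

Two structural rules tie the arms together: the dermatitis ->
gauze-and-tape move is pooled across both arms (row 5 is renormalised
from pooled counts), and the intervention arm's gauze-and-tape rows
are copied from the reference arm, whose dressing those patients
effectively wear.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .states import (
    ABSORBING_STATES,
    ARM_CHG,
    ARM_NONCHG,
    ARMS,
    HORIZON,
    N_STATES,
    TransitionMatrixSet,
)

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("patient_id", "arm", "day", "state")


class RecordError(ValueError):
    """Raised for malformed patient-day records."""


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise RecordError(f"records missing columns: {sorted(missing)}")
    df = records.loc[:, list(RECORD_COLUMNS)].copy()
    if len(df) == 0:
        return df
    if not np.issubdtype(np.asarray(df["day"]).dtype, np.number):
        raise RecordError("day column must be numeric")
    if (df["day"] < 1).any() or (df["day"] % 1 != 0).any():
        raise RecordError("days must be integers >= 1")
    df["day"] = df["day"].astype(int)
    bad_states = ~df["state"].isin(range(1, N_STATES + 1))
    if bad_states.any():
        raise RecordError(
            f"unknown state ids: {sorted(df.loc[bad_states, 'state'].unique())}"
        )
    bad_arms = ~df["arm"].isin(ARMS)
    if bad_arms.any():
        raise RecordError(
            f"unknown arms: {sorted(df.loc[bad_arms, 'arm'].unique())}"
        )
    if df.duplicated(["patient_id", "day"]).any():
        dupes = df[df.duplicated(["patient_id", "day"], keep=False)]
        pid = dupes["patient_id"].iloc[0]
        raise RecordError(f"duplicate (patient_id, day) rows, e.g. patient {pid!r}")
    return df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def preprocess_records(records: pd.DataFrame, horizon: int = HORIZON) -> pd.DataFrame:
    """Censor at the horizon, re-attribute post-discharge CRBSIs, enforce permanence."""
    df = _check_records(records)
    df = df[df["day"] <= horizon].copy()
    if len(df) == 0:
        return df.reset_index(drop=True)

    # first absorbing day per patient (before re-attribution)
    absorbing = df["state"].isin(ABSORBING_STATES)
    first_abs = (
        df[absorbing].groupby("patient_id")["day"].min().rename("first_abs")
    )
    df = df.merge(first_abs, on="patient_id", how="left")

    # patients with a discharge followed by a CRBSI within two days
    discharge_day = (
        df[df["state"] == 7].groupby("patient_id")["day"].min().rename("d7")
    )
    work = df.merge(discharge_day, on="patient_id", how="left")
    late_crbsi = work[
        work["d7"].notna()
        & work["state"].isin((3, 4))
        & (work["day"] > work["d7"])
        & (work["day"] <= work["d7"] + 2)
    ]
    if len(late_crbsi):
        frames = [df[~df["patient_id"].isin(late_crbsi["patient_id"].unique())]]
        for pid, grp in late_crbsi.groupby("patient_id"):
            sub = df[df["patient_id"] == pid].copy()
            d7 = int(grp["d7"].iloc[0])
            crbsi_state = int(grp.sort_values("day")["state"].iloc[0])
            # infection attributed to the discharge day; discharge deferred
            sub = sub[~sub["day"].isin(range(d7, d7 + 3))]
            arm = records.loc[records["patient_id"] == pid, "arm"].iloc[0]
            new_rows = [{"patient_id": pid, "arm": arm, "day": d7,
                         "state": crbsi_state, "first_abs": d7 + 1}]
            if d7 + 1 <= horizon:
                new_rows.append({"patient_id": pid, "arm": arm, "day": d7 + 1,
                                 "state": 7, "first_abs": d7 + 1})
            sub["first_abs"] = d7 + 1
            frames.append(pd.concat([sub, pd.DataFrame(new_rows)], ignore_index=True))
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)

    # permanence: after the first absorbing day, keep only repeats of that state
    absorbing_state = (
        df[df["state"].isin(ABSORBING_STATES)]
        .sort_values("day")
        .groupby("patient_id")["state"]
        .first()
        .rename("abs_state")
    )
    first_abs2 = (
        df[df["state"].isin(ABSORBING_STATES)]
        .groupby("patient_id")["day"]
        .min()
        .rename("first_abs2")
    )
    df = df.drop(columns=["first_abs"]).merge(
        absorbing_state, on="patient_id", how="left"
    ).merge(first_abs2, on="patient_id", how="left")
    after = df["first_abs2"].notna() & (df["day"] > df["first_abs2"])
    keep = ~after | (df["state"] == df["abs_state"])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d post-absorption records violating permanence", n_dropped)
    df = df[keep].drop(columns=["abs_state", "first_abs2"])
    return df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def _transition_counts(df: pd.DataFrame, horizon: int) -> np.ndarray:
    """``counts[t - 1, i - 1, j - 1]`` over consecutive recorded day pairs."""
    counts = np.zeros((horizon, N_STATES, N_STATES))
    if len(df) == 0:
        return counts
    g = df.sort_values(["patient_id", "day"], kind="stable")
    same_patient = g["patient_id"].shift(-1) == g["patient_id"]
    consecutive = g["day"].shift(-1) == g["day"] + 1
    src = g[same_patient & consecutive]
    dst = g.shift(-1)[same_patient & consecutive]
    days = src["day"].to_numpy(dtype=int)
    mask = days <= horizon - 1  # transition t -> t+1 needs t+1 within horizon
    np.add.at(
        counts,
        (
            days[mask] - 1,
            src["state"].to_numpy(dtype=int)[mask] - 1,
            dst["state"].to_numpy(dtype=int)[mask] - 1,
        ),
        1.0,
    )
    return counts


def _rows_from_counts(counts: np.ndarray, state: int) -> tuple[np.ndarray, list[int]]:
    """Per-day rows for one state with the empty-row fallback.

    Empty (day, state) rows copy the nearest earlier day with data,
    else the time-pooled row for the state, else a unit self-loop.
    Returns the ``(horizon, 8)`` rows and the list of fallback days.
    """
    horizon = counts.shape[0]
    i = state - 1
    rows = np.zeros((horizon, N_STATES))
    totals = counts[:, i, :].sum(axis=1)
    pooled = counts[:, i, :].sum(axis=0)
    pooled_row = pooled / pooled.sum() if pooled.sum() > 0 else None
    fallback_days: list[int] = []
    last_good: np.ndarray | None = None
    for t in range(horizon):
        if totals[t] > 0:
            rows[t] = counts[t, i, :] / totals[t]
            last_good = rows[t]
        else:
            fallback_days.append(t + 1)
            if last_good is not None:
                rows[t] = last_good
            elif pooled_row is not None:
                rows[t] = pooled_row
            else:
                rows[t, i] = 1.0
    return rows, fallback_days


def estimate_matrices(
    records: pd.DataFrame, arm: str, horizon: int = HORIZON
) -> TransitionMatrixSet:
    """Count-ratio estimate of one arm's daily matrices from preprocessed records.

    ``records`` may (and for the pooling rules should) contain both
    arms; rows are estimated from the requested arm's transitions
    except for the pooled dermatitis row and the gauze-and-tape rows,
    which always derive from the reference arm (see module docstring).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    df = _check_records(records)
    counts_by_arm = {
        a: _transition_counts(df[df["arm"] == a], horizon) for a in ARMS
    }
    own = counts_by_arm[arm]
    pooled_counts = counts_by_arm[ARM_CHG] + counts_by_arm[ARM_NONCHG]

    P = np.zeros((horizon, N_STATES, N_STATES))
    all_fallbacks: dict[int, list[int]] = {}
    for s in (1, 2, 3, 4):
        P[:, s - 1, :], fb = _rows_from_counts(own, s)
        if fb:
            all_fallbacks[s] = fb
    # dermatitis row pooled across arms; gauze-and-tape rows from the
    # reference arm
    P[:, 4, :], fb5 = _rows_from_counts(pooled_counts, 5)
    if fb5:
        all_fallbacks[5] = fb5
    P[:, 5, :], fb6 = _rows_from_counts(counts_by_arm[ARM_NONCHG], 6)
    if fb6:
        all_fallbacks[6] = fb6
    for s in ABSORBING_STATES:
        P[:, s - 1, s - 1] = 1.0

    for s, days in all_fallbacks.items():
        logger.info(
            "arm %s state %d: fallback rows on %d day(s) without occupants "
            "(first: day %d)",
            arm, s, len(days), days[0],
        )
    return TransitionMatrixSet(arm=arm, P=P)
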