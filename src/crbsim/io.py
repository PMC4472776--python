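"""Reading and writing the package's file formats.

* Matrix CSV: columns ``day, from_state, to_state, probability`` (all
  1-based), one file per arm; (from, to) pairs absent for a day read
  as probability 0.
* Records CSV: columns ``patient_id, arm, day, state``.
* Cost parameters / calibration targets: YAML (or JSON, a YAML subset)
  mappings using the dataclass field names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .costs import CostParameters
from .states import HORIZON, N_STATES, TransitionMatrixSet
from .synthetic import ArmHazards, ArmTargets, CalibrationTargets, HazardParameters

MATRIX_COLUMNS = ("day", "from_state", "to_state", "probability")


def read_matrix_csv(path: str | Path, arm: str, horizon: int | None = None
                    ) -> TransitionMatrixSet:
    df = pd.read_csv(path)
    missing = set(MATRIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"matrix CSV missing columns: {sorted(missing)}")
    if horizon is None:
        horizon = int(df["day"].max()) if len(df) else HORIZON
    P = np.zeros((horizon, N_STATES, N_STATES))
    day = df["day"].to_numpy(dtype=int)
    i = df["from_state"].to_numpy(dtype=int)
    j = df["to_state"].to_numpy(dtype=int)
    if (day < 1).any() or (day > horizon).any():
        raise ValueError("day outside 1..horizon in matrix CSV")
    if ((i < 1) | (i > N_STATES) | (j < 1) | (j > N_STATES)).any():
        raise ValueError("state ids outside 1..8 in matrix CSV")
    P[day - 1, i - 1, j - 1] = df["probability"].to_numpy(dtype=float)
    return TransitionMatrixSet(arm=arm, P=P)


def write_matrix_csv(matrices: TransitionMatrixSet, path: str | Path) -> None:
    """Write non-zero entries only, 12 significant digits."""
    t, i, j = np.nonzero(matrices.P)
    df = pd.DataFrame(
        {
            "day": t + 1,
            "from_state": i + 1,
            "to_state": j + 1,
            "probability": matrices.P[t, i, j],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_records_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_cost_parameters(path: str | Path) -> CostParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return CostParameters(**data)


def write_cost_parameters(params: CostParameters, path: str | Path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def _arm_targets(data: dict) -> ArmTargets:
    return ArmTargets(**data)


def read_calibration_targets(path: str | Path) -> CalibrationTargets:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CalibrationTargets(
        chg=_arm_targets(data["CHG"]), nonchg=_arm_targets(data["nonCHG"])
    )


def read_hazard_parameters(path: str | Path) -> HazardParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh)

    def arm(d: dict) -> ArmHazards:
        return ArmHazards(
            h_discharge=tuple(d["h_discharge"]),
            h_death=tuple(d["h_death"]),
            crbsi_h0=d["crbsi_h0"],
            crbsi_slope=d["crbsi_slope"],
            h_derm=d["h_derm"],
            h_newct=d["h_newct"],
            crbsi_newct_frac=d["crbsi_newct_frac"],
        )

    return HazardParameters(
        chg=arm(data["CHG"]),
        nonchg=arm(data["nonCHG"]),
        bands=tuple(tuple(b) for b in data["bands"]),
        horizon=data.get("horizon", HORIZON),
    )


def write_hazard_parameters(params: HazardParameters, path: str | Path) -> None:
    def arm(h: ArmHazards) -> dict:
        return {
            "h_discharge": [float(x) for x in h.h_discharge],
            "h_death": [float(x) for x in h.h_death],
            "crbsi_h0": float(h.crbsi_h0),
            "crbsi_slope": float(h.crbsi_slope),
            "h_derm": float(h.h_derm),
            "h_newct": float(h.h_newct),
            "crbsi_newct_frac": float(h.crbsi_newct_frac),
        }

    data = {
        "CHG": arm(params.chg),
        "nonCHG": arm(params.nonchg),
        "bands": [list(b) for b in params.bands],
        "horizon": params.horizon,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
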