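"""Shipped reference fixtures: calibrated matrices, hazards and targets.

The package ships synthetic transition matrices for both dressing
arms, calibrated (see :mod:`crbsim.synthetic`) so that the simulated
cohort occupancy reproduces the published 30-day ICU occupancy profile
of the source trial's model: roughly 3.1 vs 14.8 CRBSI patients per
1,000, 604 vs 613 discharges, 264 vs 271 deaths, and 12.91 vs 12.72
mean ICU days in the intervention vs reference arm.  They are
calibrated emulations of the original (unpublished) matrices, not the
matrices themselves.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .costs import CostParameters
from .states import ARMS, TransitionMatrixSet
from .synthetic import CalibrationTargets, HazardParameters

_DATA = resources.files(__package__) / "data"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def load_reference_matrices(arm: str) -> TransitionMatrixSet:
    """Calibrated synthetic daily matrices for one arm."""
    from .io import read_matrix_csv

    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    suffix = "chg" if arm == "CHG" else "nonchg"
    return read_matrix_csv(_data_path(f"matrices_{suffix}.csv"), arm=arm)


def load_reference_hazards() -> HazardParameters:
    """Calibrated hazards from which the shipped matrices were generated."""
    from .io import read_hazard_parameters

    return read_hazard_parameters(_data_path("hazards.yaml"))


def load_calibration_targets() -> CalibrationTargets:
    """The per-1,000 occupancy profile the fixtures are calibrated to."""
    from .io import read_calibration_targets

    return read_calibration_targets(_data_path("calibration_targets.yaml"))


def load_base_costs() -> CostParameters:
    """Base-case unit costs (EUR 2013)."""
    from .io import read_cost_parameters

    return read_cost_parameters(_data_path("base_costs.yaml"))
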