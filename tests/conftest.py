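import pytest

from crbsim.costs import CostParameters, build_state_costs
from crbsim.datasets import (
    load_base_costs,
    load_calibration_targets,
    load_reference_hazards,
    load_reference_matrices,
)
from crbsim.states import ARM_CHG, ARM_NONCHG


@pytest.fixture(scope="session")
def base_params() -> CostParameters:
    return CostParameters()


@pytest.fixture(scope="session")
def chg_costs(base_params):
    return build_state_costs(base_params, ARM_CHG)


@pytest.fixture(scope="session")
def nonchg_costs(base_params):
    return build_state_costs(base_params, ARM_NONCHG)


@pytest.fixture(scope="session")
def ref_matrices():
    """Shipped calibrated matrices, keyed by arm."""
    return {
        ARM_CHG: load_reference_matrices(ARM_CHG),
        ARM_NONCHG: load_reference_matrices(ARM_NONCHG),
    }


@pytest.fixture(scope="session")
def ref_hazards():
    return load_reference_hazards()


@pytest.fixture(scope="session")
def ref_targets():
    return load_calibration_targets()


@pytest.fixture(scope="session")
def shipped_costs():
    return load_base_costs()
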