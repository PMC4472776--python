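"""Hazard-driven matrix generation, calibration and record generation."""

import numpy as np
import pytest

from crbsim.simulate import expected_occupancy, simulate_cohort
from crbsim.states import ARM_CHG, ARM_NONCHG, validate_matrices
from crbsim.synthetic import (
    ArmHazards,
    ArmTargets,
    CalibrationTargets,
    HazardError,
    HazardParameters,
    calibrate,
    cohort_summaries,
    generate_matrices,
    generate_records,
    _targets_dict,
)


def arm_hazards(**kw) -> ArmHazards:
    defaults = dict(
        h_discharge=(0.0, 0.0, 0.0), h_death=(0.0, 0.0, 0.0),
        crbsi_h0=0.0, crbsi_slope=0.0, h_derm=0.0, h_newct=0.0,
        crbsi_newct_frac=1.0,
    )
    defaults.update(kw)
    return ArmHazards(**defaults)


def both_arms(**kw) -> HazardParameters:
    return HazardParameters(chg=arm_hazards(**kw), nonchg=arm_hazards(**kw))


def test_zero_hazards_keep_everyone_in_state_one():
    m = generate_matrices(both_arms(), ARM_CHG)
    assert validate_matrices(m).ok
    pi = expected_occupancy(m)
    assert np.allclose(pi[:, 0], 1.0)


def test_certain_discharge_absorbs_everyone_after_one_day(chg_costs):
    hp = both_arms(h_discharge=(1.0, 0.0, 0.0))
    m = generate_matrices(hp, ARM_CHG)
    res = simulate_cohort(m, chg_costs, 200, seed=1)
    assert res.mean_icu_days == 1.0
    assert res.ever_counts[6] == 200


def test_generated_matrices_always_validate(ref_hazards):
    for arm in (ARM_CHG, ARM_NONCHG):
        assert validate_matrices(generate_matrices(ref_hazards, arm)).ok


def test_dermatitis_routes_to_gauze_and_tape(ref_hazards):
    m = generate_matrices(ref_hazards, ARM_CHG)
    assert np.allclose(m.P[:, 4, 5], 1.0)


def test_gauze_rows_follow_reference_arm(ref_hazards):
    chg = generate_matrices(ref_hazards, ARM_CHG)
    ref = generate_matrices(ref_hazards, ARM_NONCHG)
    assert np.allclose(chg.P[:, 5, :], ref.P[:, 5, :])


def test_excess_hazard_sum_errors_name_the_day():
    hp = both_arms(h_discharge=(0.6, 0.0, 0.0), h_death=(0.6, 0.0, 0.0))
    with pytest.raises(HazardError, match="day 1"):
        generate_matrices(hp, ARM_CHG)


def test_crbsi_hazard_ramp_is_monotone(ref_hazards):
    for arm in (ARM_CHG, ARM_NONCHG):
        h = ref_hazards.arm(arm)
        hazards = [h.h_crbsi(t) for t in range(1, 31)]
        assert all(b >= a for a, b in zip(hazards, hazards[1:]))


def test_negative_slope_rejected():
    with pytest.raises(HazardError, match="slope"):
        arm_hazards(crbsi_slope=-1e-4)


def test_infeasible_targets_rejected():
    with pytest.raises(ValueError, match="exceed"):
        ArmTargets(
            ever_newct=0, ever_crbsi_noct=0, ever_crbsi_ct=0, ever_derm=0,
            ever_gauze=0, discharged=700, died=400, icu_days=10,
            days_to_discharge=15, days_to_death=20,
        )


def _targets_from_summaries(s: dict, frac: float) -> ArmTargets:
    return ArmTargets(
        ever_newct=s["ever_newct"],
        ever_crbsi_noct=s["ever_crbsi"] * (1 - frac),
        ever_crbsi_ct=s["ever_crbsi"] * frac,
        ever_derm=s["ever_derm"],
        ever_gauze=s["ever_gauze"],
        discharged=s["discharged"],
        died=s["died"],
        icu_days=s["icu_days"],
        days_to_discharge=s["days_to_discharge"],
        days_to_death=s["days_to_death"],
    )


def test_calibration_recovers_known_parameter_targets(ref_hazards):
    """Self-consistency: targets generated from known hazards are refit to <1%."""
    targets = CalibrationTargets(
        chg=_targets_from_summaries(
            cohort_summaries(generate_matrices(ref_hazards, ARM_CHG)),
            ref_hazards.chg.crbsi_newct_frac,
        ),
        nonchg=_targets_from_summaries(
            cohort_summaries(generate_matrices(ref_hazards, ARM_NONCHG)),
            ref_hazards.nonchg.crbsi_newct_frac,
        ),
    )
    result = calibrate(targets, seed=7, n_restarts=1)
    for arm in (ARM_CHG, ARM_NONCHG):
        fit = result.summaries(arm)
        want = _targets_dict(targets.arm(arm))
        for key, target in want.items():
            if target == 0:
                continue
            assert abs(fit[key] - target) / target < 0.01, (arm, key)


def test_calibration_trace_is_non_increasing(ref_targets):
    result = calibrate(ref_targets, seed=5, max_evals=600, n_restarts=0)
    for arm, trace in result.trace.items():
        diffs = np.diff(np.asarray(trace))
        assert (diffs <= 0).all(), arm


def test_shipped_fixtures_match_their_hazards(ref_hazards, ref_matrices):
    for arm in (ARM_CHG, ARM_NONCHG):
        regenerated = generate_matrices(ref_hazards, arm)
        assert np.allclose(ref_matrices[arm].P, regenerated.P, atol=1e-9)


def test_shipped_fixtures_reproduce_reference_profile(ref_matrices, ref_targets):
    """Calibrated matrices hit every occupancy target within 5% relative error."""
    for arm in (ARM_CHG, ARM_NONCHG):
        fit = cohort_summaries(ref_matrices[arm])
        want = _targets_dict(ref_targets.arm(arm))
        for key, target in want.items():
            if target == 0:
                continue
            assert abs(fit[key] - target) / target < 0.05, (arm, key)


def test_generate_records_degenerate_chain():
    from helpers import deterministic_chain

    m = deterministic_chain({1: 7})
    df = generate_records(m, n=3, seed=1)
    assert len(df) == 6  # state 1 then discharge, per patient
    assert set(df.patient_id) == {1, 2, 3}
    assert all(
        states == [1, 7]
        for states in df.groupby("patient_id")["state"].apply(list)
    )


def test_generate_records_empty_stream():
    from helpers import deterministic_chain

    df = generate_records(deterministic_chain({}), n=0, seed=1)
    assert len(df) == 0
    assert list(df.columns) == ["patient_id", "arm", "day", "state"]


def test_generated_records_respect_absorbing_permanence(ref_matrices):
    df = generate_records(ref_matrices[ARM_NONCHG], n=500, seed=3)
    last = df.sort_values(["patient_id", "day"]).groupby("patient_id").tail(1)
    # records stop at the first absorbing day: at most one absorbing row each
    absorbed = df[df.state >= 7]
    assert absorbed.groupby("patient_id").size().max() == 1
    assert (last.day <= 30).all()
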