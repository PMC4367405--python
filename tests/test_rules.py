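"""Posture-error rules: tolerance bands, strictness, monotonicity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneerehab.kinematics import AngleMeasures
from kneerehab.rules import (
    ERROR_LABELS,
    ThresholdConfig,
    assess_repetition,
    assess_session,
)


def measures(**kwargs) -> AngleMeasures:
    base = dict(
        thigh_raise=45.0,
        shank_raise=45.0,
        knee_flexion=0.0,
        hip_external_rotation=0.0,
        trunk_bend=0.0,
        squat_angle=45.0,
        shank_terminal=0.0,
        knee_initial_flexion=25.0,
    )
    base.update(kwargs)
    return AngleMeasures(**base)


def test_proper_slr_passes_all_rules():
    result = assess_repetition(
        "SLR", measures(thigh_raise=50.0, knee_flexion=5.0, hip_external_rotation=3.0)
    )
    assert result.errors == ()
    assert result.is_proper


def test_slr_raise_outside_ten_degree_band_is_flagged():
    result = assess_repetition("SLR", measures(thigh_raise=30.0))
    assert result.error_set == {"raise_angle_deviation"}  # |30 - 45| = 15 > 10


def test_qsm_reports_both_errors_at_once():
    result = assess_repetition(
        "QSM", measures(trunk_bend=20.0, squat_angle=20.0)
    )
    assert result.error_set == {"trunk_bent_forward", "squat_angle_deviation"}
    # hierarchical reporting order is fixed
    assert result.errors == ("trunk_bent_forward", "squat_angle_deviation")


@pytest.mark.parametrize(
    "exercise,kwargs",
    [
        ("SLR", dict(thigh_raise=35.0)),            # |35-45| = 10, not > 10
        ("SLR", dict(thigh_raise=55.0)),
        ("SLR", dict(knee_flexion=20.0)),
        ("SLR", dict(hip_external_rotation=20.0)),
        ("QSM", dict(trunk_bend=15.0)),
        ("QSM", dict(squat_angle=30.0)),            # |30-45| = 15, not > 15
        ("SAE", dict(knee_initial_flexion=32.0)),   # 25 + 7, not > 32
        ("SAE", dict(shank_terminal=7.0)),
    ],
)
def test_measure_exactly_at_tolerance_is_not_flagged(exercise, kwargs):
    assert assess_repetition(exercise, measures(**kwargs)).errors == ()


def test_sae_initial_flexion_rule_additive_vs_plain():
    m = measures(knee_initial_flexion=28.0)
    assert assess_repetition("SAE", m).errors == ()  # 28 < 25 + 7
    plain = ThresholdConfig(sae_initial_flexion_additive=False)
    assert assess_repetition("SAE", m, plain).error_set == {"initial_flexion_excess"}


def test_unknown_exercise_rejected():
    with pytest.raises(ValueError, match="unknown exercise"):
        assess_repetition("YOGA", measures())


@given(
    st.floats(0, 90),
    st.floats(-40, 40),
    st.floats(0, 45),
    st.floats(0, 80),
    st.floats(1.0, 30.0),
)
def test_enlarging_tolerances_never_adds_errors(raise_, rot, trunk, squat, extra):
    m = measures(
        thigh_raise=raise_, hip_external_rotation=rot, trunk_bend=trunk, squat_angle=squat
    )
    tight = ThresholdConfig()
    loose = dataclasses.replace(
        tight,
        thigh_raise_slr=tight.thigh_raise_slr + extra,
        hip_external_rotation_slr=tight.hip_external_rotation_slr + extra,
        trunk_bend_qsm=tight.trunk_bend_qsm + extra,
        squat_qsm=tight.squat_qsm + extra,
        knee_flexion_slr=tight.knee_flexion_slr + extra,
        knee_initial_flexion_sae=tight.knee_initial_flexion_sae + extra,
        shank_terminal_sae=tight.shank_terminal_sae + extra,
    )
    for exercise in ("SAE", "SLR", "QSM"):
        flagged_tight = assess_repetition(exercise, m, tight).error_set
        flagged_loose = assess_repetition(exercise, m, loose).error_set
        assert flagged_loose <= flagged_tight


def test_errors_are_scoped_to_their_exercise():
    m = measures(
        thigh_raise=10.0, knee_flexion=30.0, trunk_bend=25.0, squat_angle=10.0,
        knee_initial_flexion=40.0, shank_terminal=15.0, hip_external_rotation=30.0,
    )
    for exercise in ("SAE", "SLR", "QSM"):
        assert assess_repetition(exercise, m).error_set <= set(ERROR_LABELS[exercise])


def test_nonpositive_tolerance_rejected():
    bad = ThresholdConfig(squat_qsm=0.0)
    with pytest.raises(ValueError, match="tolerance"):
        assess_repetition("QSM", measures(), bad)


# --------------------------------------------------------------------------
# full-pipeline assessment
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_model(small_corpus_records):
    from kneerehab.classifier import train_tree

    return train_tree(
        [r.features for r in small_corpus_records],
        [r.exercise for r in small_corpus_records],
        seed=0,
    )


def test_assess_session_proper_slr_end_to_end(trained_model):
    from kneerehab.synth import SimParams, simulate_subject

    sessions = simulate_subject(params=SimParams().noise_free(), seed=13)
    slr = next(s for s in sessions if s.true_exercise == "SLR" and s.variant == "normal")
    results = assess_session(slr, trained_model)
    assert len(results) == 10
    assert all(r.exercise == "SLR" and r.is_proper for _, r in results)


def test_assess_session_flags_trunk_error_in_every_rep(trained_model):
    from kneerehab.synth import SimParams, simulate_subject

    sessions = simulate_subject(params=SimParams().noise_free(), seed=13)
    qsm = next(
        s for s in sessions
        if s.true_exercise == "QSM" and s.variant == "trunk_bent_forward"
    )
    results = assess_session(qsm, trained_model)
    assert results
    assert all("trunk_bent_forward" in r.errors for _, r in results)


def test_assess_session_static_session_returns_empty(trained_model, static_session):
    assert assess_session(static_session, trained_model) == []
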