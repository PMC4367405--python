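"""Tilt angles, robust range, gyro fusion and per-repetition measures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneerehab import (
    KinematicsParams,
    angle_measures,
    fused_inclination,
    preprocess_session,
    robust_range,
    segment_session,
    tilt_angles,
    tilt_series,
)
from kneerehab.synth import SimParams, simulate_repetition

from conftest import make_static_session


def random_unit_vectors(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def test_tilt_angles_match_arcsine_oracle():
    """For a unit gravity vector each axis tilt equals arcsin(component)."""
    for v in random_unit_vectors(100, seed=12):
        t = tilt_angles(v)
        expected = np.degrees(np.arcsin(v))
        np.testing.assert_allclose([t.rho, t.phi, t.theta], expected, atol=1e-9)


@pytest.mark.parametrize(
    "vec,expected",
    [
        ((0.0, 1.0, 0.0), (0.0, 90.0, 0.0)),
        ((np.sqrt(0.5), np.sqrt(0.5), 0.0), (45.0, 45.0, 0.0)),
        ((1.0, 0.0, 0.0), (90.0, 0.0, 0.0)),
    ],
)
def test_tilt_angles_axis_aligned(vec, expected):
    t = tilt_angles(vec)
    np.testing.assert_allclose([t.rho, t.phi, t.theta], expected, atol=1e-9)


@given(st.floats(1e-3, 1e3))
def test_tilt_angles_scale_invariant(scale):
    v = np.array([0.3, -0.5, 0.81])
    a, b = tilt_angles(v), tilt_angles(v * scale)
    np.testing.assert_allclose([a.rho, a.phi, a.theta], [b.rho, b.phi, b.theta], atol=1e-9)


def test_tilt_angles_zero_vector_raises():
    with pytest.raises(ValueError, match="gravity"):
        tilt_angles((0.0, 0.0, 0.0))


def test_tilt_series_agrees_with_scalar_path():
    vs = random_unit_vectors(50, seed=5)
    series = tilt_series(vs)
    for row, v in zip(series, vs):
        t = tilt_angles(v)
        np.testing.assert_allclose(row, [t.rho, t.phi, t.theta], atol=1e-12)


# --------------------------------------------------------------------------
# robust range
# --------------------------------------------------------------------------


def test_robust_range_of_1_to_100_at_ten_percent():
    assert robust_range(np.arange(1.0, 101.0), 10.0) == pytest.approx(90.0)


def test_robust_range_constant_is_zero():
    assert robust_range(np.full(37, 4.2), 10.0) == 0.0


@given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=80), st.floats(0.5, 50.0))
def test_robust_range_bounded_by_plain_range(values, x):
    series = np.asarray(values)
    rr = robust_range(series, x)
    span = float(np.max(series) - np.min(series))
    assert rr <= span + 1e-9
    if x / 100.0 * series.size <= 1:
        assert rr == pytest.approx(span)


def test_robust_range_rejects_bad_inputs():
    with pytest.raises(ValueError):
        robust_range(np.array([]), 10.0)
    with pytest.raises(ValueError):
        robust_range(np.ones(5), 80.0)


# --------------------------------------------------------------------------
# gyroscope fusion
# --------------------------------------------------------------------------


def test_fused_inclination_static_reduces_to_accelerometer_angle():
    """With zero angular velocity the recovered gravity is -O, so a vertical
    long axis (O_y = +1) reads zero inclination."""
    n = 200
    accel = np.tile([0.0, 1.0, 0.0], (n, 1))
    gyro = np.zeros((n, 3))
    incl = fused_inclination(accel, gyro, 0.25, 40.0)
    np.testing.assert_allclose(incl, 0.0, atol=1e-9)
    # horizontal long axis
    accel_h = np.tile([1.0, 0.0, 0.0], (n, 1))
    np.testing.assert_allclose(fused_inclination(accel_h, gyro, 0.25, 40.0), 90.0, atol=1e-9)


def test_fused_inclination_requires_gyro_and_lever_arm():
    accel = np.zeros((10, 3))
    with pytest.raises(ValueError):
        fused_inclination(accel, None, 0.25, 40.0)
    with pytest.raises(ValueError, match="r_HT"):
        fused_inclination(accel, np.zeros((10, 3)), 0.0, 40.0)


def test_fused_inclination_tracks_pendulum_truth():
    """Hip-pivot thigh rotation with known lever arm: the gyro-corrected
    inclination stays within 2 degrees RMS of the simulator's exact truth."""
    session, truth = simulate_repetition("SLR", "normal", SimParams(), seed=5)
    prepped = preprocess_session(session)
    stream = prepped.streams["thigh"]
    incl = fused_inclination(stream.accel, stream.gyro_smooth, 0.25, 40.0)
    rms = np.sqrt(np.mean((incl - truth["thigh_inclination"]) ** 2))
    assert rms < 2.0


def test_fused_inclination_constant_rotation_centripetal_only():
    """Uniform rotation (zero angular acceleration) exercises the pure
    centripetal branch of the rotational-acceleration formula."""
    from kneerehab.synth import _rotations, _stream_from_orientation

    rate, lever = 40.0, 0.25
    t = np.arange(0, 10.0, 1 / rate)
    elev = 36.0 * t  # constant 36 deg/s sweep
    R = _rotations(elev, np.zeros_like(elev))
    accel, gyro, _ = _stream_from_orientation(
        R, lever, rate, np.random.default_rng(0), 0.0, 0.0
    )
    incl = fused_inclination(accel, gyro, lever, rate)
    truth = 90.0 - elev
    # inclination folds at 0/180 but within the first quarter-turn it is exact
    core = slice(10, int(rate * 2.4))
    assert np.max(np.abs(incl[core] - truth[core])) < 0.2


# --------------------------------------------------------------------------
# per-repetition angle measures
# --------------------------------------------------------------------------


def _measures_for(session, config_params=None):
    prepped = preprocess_session(session)
    reps = segment_session(prepped)
    assert reps, "expected at least one repetition"
    return [angle_measures(prepped, r, params=config_params) for r in reps]


def test_standard_slr_recovers_raise_and_straight_knee():
    session, _ = simulate_repetition("SLR", "normal", SimParams().noise_free(), seed=1)
    m = _measures_for(session)[0]
    assert m.thigh_raise == pytest.approx(45.0, abs=2.0)
    assert m.knee_flexion == pytest.approx(0.0, abs=2.0)
    assert abs(m.hip_external_rotation) < 2.0


def test_qsm_trunk_lean_recovered():
    session, _ = simulate_repetition(
        "QSM", "trunk_bent_forward", SimParams().noise_free(), seed=1
    )
    m = _measures_for(session)[0]
    assert m.trunk_bend == pytest.approx(20.0, abs=2.0)


def test_fused_angle_method_matches_tilt_method_on_slr():
    session, _ = simulate_repetition("SLR", "normal", SimParams(), seed=8)
    tilt = _measures_for(session, KinematicsParams(angle_method="tilt"))[0]
    fused = _measures_for(session, KinematicsParams(angle_method="fused"))[0]
    # the fused estimate differentiates the gyro stream, so it carries a bit
    # more high-frequency noise than the low-passed tilt path
    assert fused.thigh_raise == pytest.approx(tilt.thigh_raise, abs=3.0)


def test_static_repetition_has_zero_excursions():
    session = make_static_session(n=400, gravity_vec=(0.3, 0.9, 0.1))
    prepped = preprocess_session(session)
    m = angle_measures(prepped, (0, 400))
    assert abs(m.thigh_raise) < 0.5
    assert abs(m.trunk_bend) < 0.5
    assert abs(m.hip_external_rotation) < 0.5


def test_degenerate_repetition_rejected(static_session):
    prepped = preprocess_session(static_session)
    with pytest.raises(ValueError, match="degenerate"):
        angle_measures(prepped, (0, 5))


def test_amplitude_recovery_small_sample():
    """Mean absolute amplitude error stays below 2 degrees at default noise."""
    rng = np.random.default_rng(21)
    errors = []
    for _ in range(15):
        amp = rng.uniform(20.0, 60.0)
        params = SimParams()
        params.amplitude_jitter = 0.0
        params.placement_misalignment = 0.0
        session, _ = simulate_repetition(
            "SLR", "normal", params, seed=int(rng.integers(2**31)), amplitude=amp
        )
        m = _measures_for(session)[0]
        errors.append(abs(m.thigh_raise - amp))
    assert np.mean(errors) < 2.0
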