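"""Tilt angles, gyroscope-fused inclination and per-repetition angle measures.

Orientation is read from the gravity component of the accelerometer.  With
acceleration in g, the tilt angles of the three sensor axes against the
horizontal plane are

    rho   = atan(Ax / sqrt(Ay^2 + Az^2))        (x axis)
    phi   = atan(Ay / sqrt(Ax^2 + Az^2))        (y axis)
    theta = atan(Az / sqrt(Ax^2 + Ay^2))        (z axis)

Sensors are mounted with the y axis along the segment's long axis, so ``phi``
is the signed segment elevation; ``rho`` tracks the sagittal pitch of the
anterior-pointing x axis.  Excursions are summarized per repetition by a
robust range: median of the X% largest samples minus median of the X%
smallest, which cancels baseline offsets from sensor placement and resists
residual spikes.

A second, gyroscope-fused path recovers the gravity vector during motion by
subtracting the rigid-body rotational acceleration about the proximal joint
(lever arm ``r_HT``) from the accelerometer output, then converts the
per-axis gravity into an inclination angle against the vertical.

All public angles are degrees; radians are used internally.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .signal_io import Session

logger = logging.getLogger(__name__)

GRAVITY_MS2 = 9.80665

#: arccos argument overshoot tolerated silently before a warning is logged
ARCCOS_CLAMP_TOL = 0.02


@dataclasses.dataclass
class TiltAngles:
    """Per-sample tilt angles of the three sensor axes vs. the ground, degrees."""

    rho: float
    phi: float
    theta: float


@dataclasses.dataclass
class KinematicsParams:
    """Angle-computation settings.

    x_percent:   tail fraction (percent) used by the robust range statistic.
    r_ht_m:      hip-to-thigh-sensor lever arm in meters (fused path).
    angle_method: ``tilt`` (accelerometer-only) or ``fused`` (gyro-corrected
                 thigh inclination).
    edge_fraction: fraction of the repetition window treated as its
                 initial/terminal phase.
    """

    x_percent: float = 10.0
    r_ht_m: float = 0.25
    angle_method: str = "tilt"
    edge_fraction: float = 0.10


@dataclasses.dataclass
class AngleMeasures:
    """Per-repetition scalar angle measures, degrees.

    ``knee_flexion`` follows the convention thigh_raise - shank_raise (the
    shank lags the thigh by the flexion angle when the knee is bent).
    """

    thigh_raise: float
    shank_raise: float
    knee_flexion: float
    hip_external_rotation: float
    trunk_bend: float
    squat_angle: float
    shank_terminal: float
    knee_initial_flexion: float


def tilt_angles(gravity_vec) -> TiltAngles:
    """Tilt angles of one gravity sample (Ax, Ay, Az), any consistent scale.

    Scale-invariant; raises on a (near-)zero vector, which carries no
    gravity reference.
    """
    v = np.asarray(gravity_vec, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm < 1e-12:
        raise ValueError("no gravity reference: zero acceleration vector")
    ax, ay, az = v
    rho = math.degrees(math.atan2(ax, math.hypot(ay, az)))
    phi = math.degrees(math.atan2(ay, math.hypot(ax, az)))
    theta = math.degrees(math.atan2(az, math.hypot(ax, ay)))
    return TiltAngles(rho=rho, phi=phi, theta=theta)


def tilt_series(gravity: np.ndarray) -> np.ndarray:
    """Vectorized tilt angles for an (n, 3) gravity array -> (n, 3) degrees.

    Columns are (rho, phi, theta) for the x, y, z axes.
    """
    g = np.asarray(gravity, dtype=float)
    norms = np.linalg.norm(g, axis=1)
    if np.any(norms < 1e-12):
        idx = int(np.argmin(norms))
        raise ValueError(f"no gravity reference: zero vector at sample {idx}")
    out = np.empty_like(g)
    for j in range(3):
        others = np.sqrt(np.sum(np.delete(g, j, axis=1) ** 2, axis=1))
        out[:, j] = np.degrees(np.arctan2(g[:, j], others))
    return out


#: minimum transverse gravity share for the roll angle to be well-defined
ROLL_TRANSVERSE_MIN = 0.2


def axial_roll(gravity: np.ndarray) -> np.ndarray:
    """Signed rotation about the segment's long (y) axis, degrees.

    ``atan2(-Az, Ax)`` of the gravity components: the share of gravity that
    has migrated from the anterior x axis to the mediolateral z axis.  Unlike
    the transverse tilt angles it is independent of the segment's elevation,
    so it isolates hip axial rotation from the raise itself.

    The roll is geometrically indeterminate when the long axis is (near)
    vertical -- both transverse components vanish; samples whose transverse
    gravity share falls below :data:`ROLL_TRANSVERSE_MIN` are returned as
    NaN and should be excluded from summaries.
    """
    g = np.asarray(gravity, dtype=float)
    norms = np.linalg.norm(g, axis=1)
    transverse = np.hypot(g[:, 0], g[:, 2])
    roll = np.degrees(np.arctan2(-g[:, 2], g[:, 0]))
    roll[transverse < ROLL_TRANSVERSE_MIN * np.maximum(norms, 1e-12)] = np.nan
    return roll


def robust_range(series: np.ndarray, x_percent: float = 10.0) -> float:
    """median(top m) - median(bottom m), with m = max(1, ceil(X% * N)).

    A spike/offset-resistant excursion statistic: for X*N/100 <= 1 it equals
    max - min; otherwise it is strictly smaller.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size == 0:
        raise ValueError("robust_range: empty series")
    if not 0 < x_percent <= 50:
        raise ValueError(f"x_percent must lie in (0, 50], got {x_percent}")
    m = max(1, math.ceil(x_percent / 100.0 * series.size))
    ordered = np.sort(series)
    return float(np.median(ordered[-m:]) - np.median(ordered[:m]))


def _angular_derivative(w: np.ndarray, rate: float) -> np.ndarray:
    """Central differences with one-sided boundaries, rad/s -> rad/s^2."""
    return np.gradient(w, 1.0 / rate, axis=0)


def fused_inclination(
    accel: np.ndarray,
    gyro_dps: np.ndarray,
    r_ht_m: float | np.ndarray = 0.25,
    rate: float = 40.0,
) -> np.ndarray:
    """Gyro-corrected inclination of the segment long axis vs. vertical, degrees.

    Steps: angular velocity w (rad/s) -> angular acceleration by central
    differences -> rotational acceleration of the sensor point
    ``r'' = dw/dt x r + w x (w x r)`` about the proximal joint -> recovered
    gravity ``g = r'' - O`` (accelerometer output O in g) -> inclination
    ``arccos(-g_y / ||g||)`` clamped to the arccos domain.  Samples whose
    clamp exceeds a 0.02 tolerance trigger a logged warning.

    With zero angular velocity this reduces to the accelerometer-only
    inclination ``arccos(O_y / ||O||)``.
    """
    O = np.asarray(accel, dtype=float)
    if gyro_dps is None:
        raise ValueError("fused inclination requires a gyroscope stream")
    w = np.radians(np.asarray(gyro_dps, dtype=float))
    if O.shape != w.shape:
        raise ValueError("accel and gyro must have identical shapes")
    r = np.asarray(r_ht_m, dtype=float)
    if r.ndim == 0:
        # scalar lever arm: sensor sits distal of the joint along -y
        r = np.array([0.0, -float(r), 0.0])
    if np.linalg.norm(r) <= 0:
        raise ValueError("lever arm |r_HT| must be > 0")

    wdot = _angular_derivative(w, rate)
    r_acc = np.cross(wdot, r) + np.cross(w, np.cross(w, r))  # m/s^2
    g_rec = r_acc / GRAVITY_MS2 - O  # recovered gravity, g units
    norms = np.linalg.norm(g_rec, axis=1)
    norms = np.where(norms < 1e-12, 1e-12, norms)
    ratio = -g_rec[:, 1] / norms
    overshoot = np.abs(ratio) - 1.0
    if np.any(overshoot > ARCCOS_CLAMP_TOL):
        n_bad = int(np.sum(overshoot > ARCCOS_CLAMP_TOL))
        logger.warning(
            "fused_inclination: arccos argument exceeded clamp tolerance at "
            "%d samples (max overshoot %.3f); values clamped",
            n_bad,
            float(np.max(overshoot)),
        )
    return np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))


def _edge_window(n: int, fraction: float) -> int:
    return max(1, int(round(fraction * n)))


def angle_measures(
    session: Session,
    repetition,
    x_percent: float = 10.0,
    params: KinematicsParams | None = None,
) -> AngleMeasures:
    """All per-repetition angle measures for one segmented window.

    Requires gravity streams (run :func:`~kneerehab.preprocess.preprocess_session`
    first).  Raise/bend excursions use the robust range of x-axis tilt traces;
    instantaneous knee flexion (for initial/terminal SAE angles) is the
    difference of the thigh and shank long-axis elevations; hip rotation uses
    the axial roll angle.  ``repetition`` is any object with ``start``/``end``
    sample attributes (or a (start, end) tuple).
    """
    params = params or KinematicsParams(x_percent=x_percent)
    if hasattr(repetition, "start"):
        start, end = int(repetition.start), int(repetition.end)
    else:
        start, end = int(repetition[0]), int(repetition[1])
    n = end - start
    if n < 10:
        raise ValueError(f"degenerate repetition: {n} samples (< 10)")
    if not 0 <= start < end <= session.n_samples:
        raise ValueError(f"repetition [{start}, {end}) outside session bounds")

    grav = {}
    for site in ("chest", "thigh", "shank"):
        g = session.streams[site].gravity
        if g is None:
            raise ValueError("gravity streams not computed; run preprocess_session")
        grav[site] = g[start:end]

    tilts = {site: tilt_series(g) for site, g in grav.items()}
    x = params.x_percent

    # Excursions are measured on the signed long-axis (y) elevation: in
    # planar motion its range equals the transverse x-tilt range, but it is
    # invariant to axial roll (which redistributes gravity between x and z)
    # and unambiguous when a segment crosses the horizontal.
    thigh_elev = tilts["thigh"][:, 1]
    if params.angle_method == "fused":
        stream = session.streams["thigh"]
        if stream.gyro is None:
            raise ValueError("angle_method='fused' requires a gyroscope stream")
        gyro = (stream.gyro_smooth if stream.gyro_smooth is not None else stream.gyro)
        incl = fused_inclination(
            stream.accel[start:end], gyro[start:end], params.r_ht_m, session.sampling_rate
        )
        thigh_excursion = robust_range(incl, x)
    elif params.angle_method == "tilt":
        thigh_excursion = robust_range(thigh_elev, x)
    else:
        raise ValueError(f"unknown angle_method '{params.angle_method}'")

    shank_raise = robust_range(tilts["shank"][:, 1], x)
    trunk_bend = robust_range(tilts["chest"][:, 1], x)
    roll = axial_roll(grav["thigh"])
    roll = roll[np.isfinite(roll)]  # drop near-vertical (indeterminate) samples
    rotation = robust_range(roll, x) if roll.size else 0.0

    # signed elevations of the long axes -> instantaneous knee flexion
    flexion = tilts["thigh"][:, 1] - tilts["shank"][:, 1]
    k = _edge_window(n, params.edge_fraction)
    knee_initial_flexion = float(np.median(flexion[:k]))
    # Repetition windows run rest-to-rest, so the movement's terminal posture
    # (peak knee extension) is the low-flexion extreme inside the window, not
    # the window's final samples; summarized robustly by the bottom decile.
    shank_terminal = float(np.median(np.sort(flexion)[:k]))

    return AngleMeasures(
        thigh_raise=thigh_excursion,
        shank_raise=shank_raise,
        knee_flexion=thigh_excursion - shank_raise,
        hip_external_rotation=rotation,
        trunk_bend=trunk_bend,
        squat_angle=thigh_excursion,
        shank_terminal=shank_terminal,
        knee_initial_flexion=knee_initial_flexion,
    )
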