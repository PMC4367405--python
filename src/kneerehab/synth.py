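"""Kinematic simulator: labeled three-site IMU sessions for every exercise variant.

The simulator stands in for subject recordings: it generates realistic
accelerometer/gyroscope streams for the chest, thigh and shank during the
three knee-OA rehabilitation exercises and their improper variants, together
with exact ground truth (repetition boundaries, per-repetition angles,
gravity vectors, thigh inclination).

Model.  Each body segment is a rigid body whose orientation is parametrized
by the elevation ``e(t)`` of its long axis above the horizontal and an axial
roll ``psi(t)`` about that axis.  Sensor frames follow the mounting
convention: y along the segment long axis (pointing proximal/up), x normal
to the anterior surface, z mediolateral.  Per repetition the joint angles
follow a raised-cosine profile ``h(t) = (1 - cos(2 pi t / T)) / 2`` -- smooth
(C1), starting and ending at the resting posture.  The accelerometer output
is the gravity projection into the sensor frame plus the translational
acceleration of the sensor point (rigid-body pivot about the proximal joint
with a configurable lever arm) plus white noise; the gyroscope output is the
exact body-frame angular velocity plus white noise.

Study protocol emulated (per subject): 3 exercises x proper/improper
variants, 10 repetitions each (20 for the SLR raise-angle variant, split 10
above / 10 below the 45 degree target), 140 repetitions total; 10 subjects
by default, each with its own cadence, amplitudes and sensor-placement
misalignment drawn once from the subject seed.

Improper-variant amplitudes sit at nominal +/- (tolerance + 5 degrees), so
errors are detectable but near-boundary repetitions occur under amplitude
jitter; at the default noise level the end-to-end pipeline is deliberately
not perfectly separable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import GRAVITY_MS2, AngleMeasures
from .signal_io import SITES, Session, SensorStream, write_session

# --------------------------------------------------------------------------
# parameters and protocol
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SimParams:
    """Simulation settings (angles in degrees, durations in seconds).

    ``rep_duration`` is the nominal repetition period; each subject draws a
    cadence within +/- ``subject_duration_jitter`` (relative) of it, and each
    repetition jitters a further +/- ``rep_duration_jitter`` around the
    subject cadence.
    """

    sampling_rate: float = 40.0
    rep_duration: float = 5.0
    subject_duration_jitter: float = 0.20
    rep_duration_jitter: float = 0.05
    noise_sigma: float = 0.02           # accel white noise, g
    gyro_noise_sigma: float = 0.5       # gyro white noise, deg/s
    placement_misalignment: float = 3.0  # per-subject/site mounting offset sd, deg
    amplitude_jitter: float = 3.0       # per-repetition amplitude sd, deg
    improper_margin: float = 5.0        # variants at nominal +/- (tolerance+margin)
    pad_s: float = 1.0                  # resting lead-in/out
    trunk_wobble: float = 2.0           # incidental trunk sway in QSM, deg
    r_ht_m: float = 0.25                # hip -> thigh sensor lever arm
    r_ks_m: float = 0.25                # knee -> shank sensor lever arm
    r_c_m: float = 0.40                 # hip -> chest sensor lever arm

    def noise_free(self) -> "SimParams":
        """Copy with every stochastic magnitude zeroed (deterministic truth)."""
        return dataclasses.replace(
            self,
            noise_sigma=0.0,
            gyro_noise_sigma=0.0,
            placement_misalignment=0.0,
            amplitude_jitter=0.0,
            subject_duration_jitter=0.0,
            rep_duration_jitter=0.0,
        )


#: (exercise, variant, repetitions) design, one session per row
PROTOCOL: tuple[tuple[str, str, int], ...] = (
    ("SAE", "normal", 10),
    ("SAE", "initial_flexion", 10),
    ("SAE", "knee_not_extended", 10),
    ("SAE", "both", 10),
    ("SLR", "normal", 10),
    ("SLR", "knee_not_extended", 10),
    ("SLR", "hip_external_rotation", 10),
    ("SLR", "raise_angle_deviation", 20),
    ("SLR", "both", 10),
    ("QSM", "normal", 10),
    ("QSM", "trunk_bent_forward", 10),
    ("QSM", "squat_angle_deviation", 10),
    ("QSM", "both", 10),
)

#: intended error-label set per (exercise, variant)
VARIANT_ERRORS: dict[tuple[str, str], frozenset[str]] = {
    ("SAE", "normal"): frozenset(),
    ("SAE", "initial_flexion"): frozenset({"initial_flexion_excess"}),
    ("SAE", "knee_not_extended"): frozenset({"knee_not_extended"}),
    ("SAE", "both"): frozenset({"initial_flexion_excess", "knee_not_extended"}),
    ("SLR", "normal"): frozenset(),
    ("SLR", "knee_not_extended"): frozenset({"knee_not_extended"}),
    ("SLR", "hip_external_rotation"): frozenset({"hip_external_rotation"}),
    ("SLR", "raise_angle_deviation"): frozenset({"raise_angle_deviation"}),
    ("SLR", "both"): frozenset({"knee_not_extended", "hip_external_rotation"}),
    ("QSM", "normal"): frozenset(),
    ("QSM", "trunk_bent_forward"): frozenset({"trunk_bent_forward"}),
    ("QSM", "squat_angle_deviation"): frozenset({"squat_angle_deviation"}),
    ("QSM", "both"): frozenset({"trunk_bent_forward", "squat_angle_deviation"}),
}

# nominal postures / amplitudes (degrees)
SLR_RAISE_NOMINAL = 45.0
SLR_KNEE_FLEXION_IMPROPER = 25.0      # 0 + (20 tolerance + 5)
SLR_ROTATION_IMPROPER = 25.0          # 0 + (20 tolerance + 5)
SLR_RAISE_HIGH = 60.0                 # 45 + (10 tolerance + 5)
SLR_RAISE_LOW = 30.0                  # 45 - (10 tolerance + 5)
SAE_THIGH_ELEVATION = 25.0            # propped over a bolster
SAE_INITIAL_FLEXION = 25.0
SAE_INITIAL_FLEXION_IMPROPER = 37.0   # 25 + (7 tolerance + 5)
SAE_TERMINAL_FLEXION_IMPROPER = 12.0  # 0 + (7 tolerance + 5)
SAE_CHEST_ELEVATION = 0.0             # supine trunk, as in the straight leg raise
QSM_SQUAT_NOMINAL = 45.0
QSM_SQUAT_IMPROPER = 25.0             # shallow squat: 45 - (15 tolerance + 5)
QSM_TRUNK_IMPROPER = 20.0             # 0 + (15 tolerance + 5)
QSM_SHANK_LEAN = 15.0                 # forward shank lean during the squat


@dataclasses.dataclass
class _SubjectContext:
    """Per-subject draws: cadence and per-site mounting misalignment."""

    cadence_s: float
    elev_offset: dict[str, float]
    roll_offset: dict[str, float]

    @classmethod
    def draw(cls, params: SimParams, rng: np.random.Generator) -> "_SubjectContext":
        cadence = params.rep_duration * (
            1.0 + rng.uniform(-params.subject_duration_jitter, params.subject_duration_jitter)
        )
        mis = params.placement_misalignment
        return cls(
            cadence_s=cadence,
            elev_offset={s: float(rng.normal(0.0, mis)) if mis > 0 else 0.0 for s in SITES},
            roll_offset={s: float(rng.normal(0.0, mis)) if mis > 0 else 0.0 for s in SITES},
        )


# --------------------------------------------------------------------------
# per-repetition joint profiles
# --------------------------------------------------------------------------


def _raised_cosine(n: int) -> np.ndarray:
    """0 -> 1 -> 0 over n samples, C1-continuous when repetitions abut."""
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / n))


@dataclasses.dataclass
class _RepSpec:
    """Resolved per-repetition profile parameters and ground-truth angles."""

    elev: dict[str, np.ndarray]   # per-site elevation, deg
    roll: dict[str, np.ndarray]   # per-site axial roll, deg
    truth: AngleMeasures


def _jitter(rng: np.random.Generator, sd: float) -> float:
    return float(rng.normal(0.0, sd)) if sd > 0 else 0.0


def _session_draws(
    exercise: str, variant: str, params: SimParams, rng: np.random.Generator
) -> dict:
    """Session-level parameter draws.

    Resting postures must be identical across the repetitions of a session
    (the signal is continuous through the rep junctions), so quantities that
    set the rest posture -- the SAE resting knee flexion -- are drawn once
    per session; peak amplitudes jitter per repetition.
    """
    draws: dict = {}
    if exercise == "SAE":
        if variant in ("initial_flexion", "both"):
            f0 = max(30.0, SAE_INITIAL_FLEXION_IMPROPER + _jitter(rng, params.amplitude_jitter))
        else:
            f0 = max(15.0, SAE_INITIAL_FLEXION + _jitter(rng, params.amplitude_jitter))
        draws["sae_f0"] = f0
    return draws


def _rep_profiles(
    exercise: str,
    variant: str,
    n: int,
    params: SimParams,
    rng: np.random.Generator,
    rep_index: int = 0,
    session_draws: dict | None = None,
) -> _RepSpec:
    """One repetition's per-site elevation/roll profiles plus truth angles."""
    session_draws = session_draws or _session_draws(exercise, variant, params, rng)
    h = _raised_cosine(n)
    zeros = np.zeros(n)
    aj = params.amplitude_jitter

    if exercise == "SLR":
        amp = session_draws.get("amplitude", SLR_RAISE_NOMINAL)
        if variant == "raise_angle_deviation":
            # first half of the set beyond 45, second half below
            amp = SLR_RAISE_HIGH if rep_index % 20 < 10 else SLR_RAISE_LOW
        amp = max(10.0, amp + _jitter(rng, aj))
        flex = 0.0
        if variant in ("knee_not_extended", "both"):
            flex = max(5.0, SLR_KNEE_FLEXION_IMPROPER + _jitter(rng, aj))
        rot = 0.0
        if variant in ("hip_external_rotation", "both"):
            rot = max(5.0, SLR_ROTATION_IMPROPER + _jitter(rng, aj))
        thigh = amp * h
        shank = (amp - flex) * h
        roll = rot * h
        truth = AngleMeasures(
            thigh_raise=amp,
            shank_raise=amp - flex,
            knee_flexion=flex,
            hip_external_rotation=rot,
            trunk_bend=0.0,
            squat_angle=amp,
            shank_terminal=0.0,
            knee_initial_flexion=0.0,
        )
        return _RepSpec(
            elev={"chest": zeros, "thigh": thigh, "shank": shank},
            roll={"chest": zeros, "thigh": roll, "shank": roll},
            truth=truth,
        )

    if exercise == "SAE":
        f0 = session_draws["sae_f0"]
        f_end = 0.0
        if variant in ("knee_not_extended", "both"):
            f_end = max(8.0, min(f0 - 5.0, SAE_TERMINAL_FLEXION_IMPROPER + _jitter(rng, aj)))
        flexion = f0 - (f0 - f_end) * h  # knee extends to f_end, returns to f0
        thigh = np.full(n, SAE_THIGH_ELEVATION)
        shank = thigh - flexion
        chest = np.full(n, SAE_CHEST_ELEVATION)
        truth = AngleMeasures(
            thigh_raise=0.0,
            shank_raise=f0 - f_end,
            knee_flexion=-(f0 - f_end),
            hip_external_rotation=0.0,
            trunk_bend=0.0,
            squat_angle=0.0,
            shank_terminal=f_end,
            knee_initial_flexion=f0,
        )
        return _RepSpec(
            elev={"chest": chest, "thigh": thigh, "shank": shank},
            roll={"chest": zeros, "thigh": zeros, "shank": zeros},
            truth=truth,
        )

    if exercise == "QSM":
        squat = session_draws.get("amplitude", QSM_SQUAT_NOMINAL)
        if variant in ("squat_angle_deviation", "both"):
            squat = QSM_SQUAT_IMPROPER
        squat = max(10.0, squat + _jitter(rng, aj))
        bend = params.trunk_wobble
        if variant in ("trunk_bent_forward", "both"):
            bend = max(5.0, QSM_TRUNK_IMPROPER + _jitter(rng, aj))
        lean = max(5.0, QSM_SHANK_LEAN + _jitter(rng, aj / 2.0))
        truth = AngleMeasures(
            thigh_raise=squat,
            shank_raise=lean,
            knee_flexion=squat - lean,
            hip_external_rotation=0.0,
            trunk_bend=bend,
            squat_angle=squat,
            shank_terminal=-(squat - lean),
            knee_initial_flexion=0.0,
        )
        return _RepSpec(
            elev={
                "chest": 90.0 - bend * h,
                "thigh": 90.0 - squat * h,
                "shank": 90.0 - lean * h,
            },
            roll={"chest": zeros, "thigh": zeros, "shank": zeros},
            truth=truth,
        )

    raise ValueError(f"unknown exercise '{exercise}'")


# --------------------------------------------------------------------------
# rigid-body signal synthesis
# --------------------------------------------------------------------------


def _rotations(elev_deg: np.ndarray, roll_deg: np.ndarray) -> np.ndarray:
    """Per-sample rotation matrices (n, 3, 3): sensor frame -> world frame.

    World: Z up.  Columns are the world coordinates of the sensor axes for a
    segment with long-axis elevation e and axial roll psi:
    y = (cos e, 0, sin e), x = (-sin e, 0, cos e) rotated about y by psi,
    z = x cross y.
    """
    e = np.radians(elev_deg)
    p = np.radians(roll_deg)
    n = e.shape[0]
    x0 = np.stack([-np.sin(e), np.zeros(n), np.cos(e)], axis=1)
    y = np.stack([np.cos(e), np.zeros(n), np.sin(e)], axis=1)
    z0 = np.cross(x0, y)
    cp, sp = np.cos(p)[:, None], np.sin(p)[:, None]
    x = cp * x0 - sp * z0
    z = sp * x0 + cp * z0
    return np.stack([x, y, z], axis=2)  # columns = axis images


def _stream_from_orientation(
    R: np.ndarray,
    lever_m: float,
    rate: float,
    rng: np.random.Generator,
    noise_sigma: float,
    gyro_noise_sigma: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(accel_g, gyro_dps, gravity_truth_g) for a pivoting rigid segment.

    The sensor sits ``lever_m`` distal of the (static) proximal joint along
    the segment long axis; its world position is p = R r with r = (0,-l,0).
    Acceleration and angular velocity are obtained by numerical
    differentiation of the exact orientation trajectory.
    """
    dt = 1.0 / rate
    r_body = np.array([0.0, -lever_m, 0.0])
    p = R @ r_body  # (n, 3)
    v = np.gradient(p, dt, axis=0)
    a_world = np.gradient(v, dt, axis=0)  # m/s^2

    g_world = np.array([0.0, 0.0, -GRAVITY_MS2])
    spec_force = a_world - g_world  # what an accelerometer measures, world frame
    accel = np.einsum("nij,nj->ni", R.transpose(0, 2, 1), spec_force) / GRAVITY_MS2
    gravity_truth = np.einsum(
        "nij,j->ni", R.transpose(0, 2, 1), -g_world
    ) / GRAVITY_MS2

    # body-frame angular velocity from Omega = R^T dR/dt (antisymmetrized)
    dR = np.gradient(R, dt, axis=0)
    omega_mat = np.einsum("nij,njk->nik", R.transpose(0, 2, 1), dR)
    omega_mat = 0.5 * (omega_mat - omega_mat.transpose(0, 2, 1))
    w = np.stack(
        [omega_mat[:, 2, 1], omega_mat[:, 0, 2], omega_mat[:, 1, 0]], axis=1
    )
    gyro = np.degrees(w)

    if noise_sigma > 0:
        accel = accel + rng.normal(0.0, noise_sigma, accel.shape)
    if gyro_noise_sigma > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sigma, gyro.shape)
    return accel, gyro, gravity_truth


_LEVERS = {"chest": "r_c_m", "thigh": "r_ht_m", "shank": "r_ks_m"}


def _assemble_session(
    exercise: str,
    variant: str,
    n_reps: int,
    params: SimParams,
    rng: np.random.Generator,
    ctx: _SubjectContext,
    subject_id: str,
    amplitude: float | None = None,
) -> Session:
    rate = params.sampling_rate
    pad = int(round(params.pad_s * rate))

    draws = _session_draws(exercise, variant, params, rng)
    if amplitude is not None:
        draws["amplitude"] = float(amplitude)
    rep_lengths = []
    specs: list[_RepSpec] = []
    for i in range(n_reps):
        T = ctx.cadence_s * (
            1.0 + (rng.uniform(-params.rep_duration_jitter, params.rep_duration_jitter)
                   if params.rep_duration_jitter > 0 else 0.0)
        )
        n = max(8, int(round(T * rate)))
        rep_lengths.append(n)
        specs.append(
            _rep_profiles(
                exercise, variant, n, params, rng, rep_index=i, session_draws=draws
            )
        )

    boundaries = [pad]
    for n in rep_lengths:
        boundaries.append(boundaries[-1] + n)
    total = boundaries[-1] + pad

    streams: dict[str, SensorStream] = {}
    gravity_truth: dict[str, np.ndarray] = {}
    elev_all: dict[str, np.ndarray] = {}
    for site in SITES:
        rest_elev = specs[0].elev[site][0]
        elev = np.full(total, rest_elev, dtype=float)
        roll = np.zeros(total, dtype=float)
        pos = pad
        for spec, n in zip(specs, rep_lengths):
            elev[pos : pos + n] = spec.elev[site]
            roll[pos : pos + n] = spec.roll[site]
            pos += n
        elev += ctx.elev_offset[site]
        roll += ctx.roll_offset[site]
        R = _rotations(elev, roll)
        accel, gyro, g_truth = _stream_from_orientation(
            R,
            getattr(params, _LEVERS[site]),
            rate,
            rng,
            params.noise_sigma,
            params.gyro_noise_sigma,
        )
        streams[site] = SensorStream(site=site, accel=accel, gyro=gyro, sampling_rate=rate)
        gravity_truth[site] = g_truth
        elev_all[site] = elev

    truth = {
        "boundaries": [(int(s), int(e)) for s, e in zip(boundaries[:-1], boundaries[1:])],
        "measures": [spec.truth for spec in specs],
        "gravity": gravity_truth,
        "elevation": elev_all,
        "thigh_inclination": 90.0 - elev_all["thigh"],
    }
    return Session(
        streams=streams,
        subject_id=subject_id,
        true_exercise=exercise,
        true_errors=VARIANT_ERRORS[(exercise, variant)],
        variant=variant,
        truth=truth,
    )


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def simulate_repetition(
    exercise: str,
    variant: str,
    params: SimParams | None = None,
    seed: int = 0,
    amplitude: float | None = None,
) -> tuple[Session, dict]:
    """One-repetition session (with resting pads) plus its ground truth.

    ``amplitude`` optionally overrides the exercise's primary nominal
    amplitude (SLR raise / QSM squat angle), e.g. for parameter-recovery
    studies across an amplitude range.
    """
    params = params or SimParams()
    if (exercise, variant) not in VARIANT_ERRORS:
        raise ValueError(f"unknown variant '{variant}' for exercise '{exercise}'")
    rng = np.random.default_rng(seed)
    ctx = _SubjectContext.draw(params, rng)
    session = _assemble_session(
        exercise, variant, 1, params, rng, ctx, "single", amplitude=amplitude
    )
    return session, session.truth


def simulate_subject(
    protocol: tuple[tuple[str, str, int], ...] | None = None,
    params: SimParams | None = None,
    seed: int = 0,
    subject_id: str = "subject01",
) -> list[Session]:
    """All protocol sessions for one subject (140 labeled repetitions by default).

    Subject-level draws (cadence, mounting misalignment) happen once from the
    seed; two calls with the same arguments are bit-identical.
    """
    protocol = protocol or PROTOCOL
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    ctx = _SubjectContext.draw(params, rng)
    sessions = []
    for exercise, variant, n_reps in protocol:
        if (exercise, variant) not in VARIANT_ERRORS:
            raise ValueError(f"unknown variant '{variant}' for exercise '{exercise}'")
        sessions.append(
            _assemble_session(exercise, variant, n_reps, params, rng, ctx, subject_id)
        )
    return sessions


def simulate_corpus(
    n_subjects: int = 10,
    params: SimParams | None = None,
    seed: int = 0,
    protocol: tuple[tuple[str, str, int], ...] | None = None,
) -> list[Session]:
    """In-memory labeled corpus: ``n_subjects`` x the full protocol.

    Distinct per-subject seeds are derived deterministically from the master
    seed via :class:`numpy.random.SeedSequence`.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a corpus")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    sessions: list[Session] = []
    for i, child in enumerate(children):
        subject_seed = int(child.generate_state(1)[0] % (2**31))
        sessions.extend(
            simulate_subject(
                protocol, params, seed=subject_seed, subject_id=f"subject{i + 1:02d}"
            )
        )
    return sessions


def simulate_dataset(
    out_dir: str | Path,
    n_subjects: int = 10,
    params: SimParams | None = None,
    seed: int = 0,
    protocol: tuple[tuple[str, str, int], ...] | None = None,
) -> Path:
    """Write a labeled corpus to disk; returns the path of ``manifest.csv``.

    Layout: ``<out>/<subject>/<exercise>_<variant>_{site}.csv`` plus one
    session manifest each, and a corpus-level ``manifest.csv`` with columns
    ``subject,session_manifest,exercise,variant,labels`` (semicolon-joined).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = simulate_corpus(n_subjects, params, seed, protocol)
    rows = []
    for session in sessions:
        sub_dir = out_dir / session.subject_id
        stem = f"{session.true_exercise}_{session.variant}"
        manifest = write_session(session, sub_dir, stem=stem)
        rows.append(
            {
                "subject": session.subject_id,
                "session_manifest": str(manifest.relative_to(out_dir)),
                "exercise": session.true_exercise,
                "variant": session.variant,
                "labels": ";".join(sorted(session.true_errors or ())),
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def load_corpus(corpus_dir: str | Path) -> list[Session]:
    """Read back a corpus written by :func:`simulate_dataset`."""
    from .signal_io import read_session

    corpus_dir = Path(corpus_dir)
    table = pd.read_csv(corpus_dir / "manifest.csv", keep_default_na=False)
    sessions = []
    for _, row in table.iterrows():
        session = read_session(corpus_dir / row["session_manifest"])
        session.subject_id = row["subject"]
        session.true_exercise = row["exercise"]
        session.variant = row["variant"]
        labels = str(row["labels"])
        session.true_errors = frozenset(l for l in labels.split(";") if l)
        sessions.append(session)
    return sessions
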