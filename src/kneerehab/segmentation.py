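"""Activity-defined repetition windows from valleys of the shank angle trace.

The three rehabilitation exercises all involve a periodic excursion of the
shank away from its resting posture and back, so repetition boundaries are
the instants where the shank angle returns to rest.  The session is divided
at the valleys of the shank's angular deviation from rest: the great-circle
angle between the instantaneous gravity direction in the shank frame and its
resting direction (estimated from the first half second of the recording,
which is assumed to begin at rest).  The deviation is zero at rest and grows
with any reorientation of the shank, so rest points are valleys for every
exercise regardless of movement direction, and the trace stays
well-conditioned even when the segment is vertical (where individual tilt
angles degenerate).

Windows adapt to each user's pace: boundaries are wherever the valleys fall,
so repetition counts are invariant to uniform time scaling of the movement.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.signal import find_peaks

from .kinematics import robust_range
from .signal_io import Session

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Repetition:
    """Half-open sample window [start, end) containing one repetition."""

    start: int
    end: int
    source_site: str = "shank"

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class SegmentationParams:
    """Valley-detection settings.

    min_prominence_deg: minimum valley prominence (and minimum window
        excursion) in degrees -- small against the >= 15 degree excursions of
        the exercises but large against filtered sensor noise.
    min_separation_s: minimum spacing between valleys.
    min_duration_s:   windows shorter than this are discarded.
    rest_window_s:    initial span used to estimate the resting angle.
    """

    min_prominence_deg: float = 5.0
    min_separation_s: float = 1.0
    min_duration_s: float = 1.0
    rest_window_s: float = 0.5


def detect_valleys(
    angle_series: np.ndarray,
    min_prominence: float = 5.0,
    min_separation: float = 1.0,
    rate: float = 40.0,
) -> np.ndarray:
    """Indices of local minima with the given prominence and spacing.

    May return an empty array (e.g. constant input).
    """
    series = np.asarray(angle_series, dtype=float)
    if series.size < 3:
        return np.empty(0, dtype=int)
    distance = max(1, int(round(min_separation * rate)))
    valleys, _ = find_peaks(-series, prominence=min_prominence, distance=distance)
    return valleys.astype(int)


def rest_rectified_trace(session: Session, params: SegmentationParams) -> np.ndarray:
    """Shank angular deviation from the resting orientation, degrees.

    Great-circle angle between the unit gravity direction at each sample and
    the resting gravity direction; non-negative, zero at rest.
    """
    gravity = session.streams["shank"].gravity
    if gravity is None:
        raise ValueError("gravity streams not computed; run preprocess_session")
    norms = np.linalg.norm(gravity, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero gravity vector in shank stream")
    unit = gravity / norms
    k = max(1, int(round(params.rest_window_s * session.sampling_rate)))
    rest = np.median(unit[:k], axis=0)
    rest = rest / np.linalg.norm(rest)
    return np.degrees(np.arccos(np.clip(unit @ rest, -1.0, 1.0)))


def segment_session(
    session: Session, params: SegmentationParams | None = None
) -> list[Repetition]:
    """Divide a preprocessed session into repetition windows.

    Consecutive valleys of the rectified shank trace delimit repetitions;
    the recording start and end act as implicit boundaries so the first and
    last repetitions are retained.  Windows shorter than ``min_duration_s``
    or with excursion below ``min_prominence_deg`` (no movement) are
    discarded.  Returns an empty list (with a logged warning) if nothing
    qualifies.
    """
    params = params or SegmentationParams()
    rate = session.sampling_rate
    trace = rest_rectified_trace(session, params)
    valleys = detect_valleys(
        trace, params.min_prominence_deg, params.min_separation_s, rate
    )
    boundaries = np.concatenate(([0], valleys, [trace.size]))
    boundaries = np.unique(boundaries)

    min_len = int(round(params.min_duration_s * rate))
    reps: list[Repetition] = []
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        if end - start < max(min_len, 2):
            continue
        if robust_range(trace[start:end], 50.0) < params.min_prominence_deg and (
            np.max(trace[start:end]) - np.min(trace[start:end])
        ) < params.min_prominence_deg:
            continue  # no movement inside the window
        reps.append(Repetition(start=int(start), end=int(end)))
    if not reps:
        logger.warning("segment_session: no repetitions found (static recording?)")
    return reps
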