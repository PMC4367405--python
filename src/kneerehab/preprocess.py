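"""Noise-spike removal and gravity-component extraction from raw acceleration.

The accelerometer signal is the sum of a gravity projection (which encodes
segment orientation) and translational/vibration components.  Each axis is
first median-filtered (3-sample window by default) to remove isolated noise
spikes, then low-pass filtered at 0.5 Hz with a zero-phase 2nd-order
Butterworth filter (applied forward-backward) to keep the gravity component
and reject the motion component.  Zero-phase filtering matters because
downstream repetition segmentation relies on the *timing* of angle valleys.

The motion ("high-pass") branch is exposed as the raw-minus-gravity residual
rather than a separate filter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal

from .signal_io import SITES, Session, SensorStream, validate_session


@dataclasses.dataclass
class FilterConfig:
    """Preprocessing parameters.

    median_order: odd window length of the spike-removal median filter.
    lpf_cutoff:   gravity low-pass cutoff in Hz (must be below Nyquist).
    lpf_order:    Butterworth order (applied forward-backward, so the
                  effective magnitude response is squared).
    """

    median_order: int = 3
    lpf_cutoff: float = 0.5
    lpf_order: int = 2

    def validate(self, sampling_rate: float) -> None:
        if self.median_order < 1 or self.median_order % 2 == 0:
            raise ValueError(f"median_order must be odd >= 1, got {self.median_order}")
        if not 0 < self.lpf_cutoff < sampling_rate / 2:
            raise ValueError(
                f"lpf_cutoff must lie in (0, Nyquist={sampling_rate / 2} Hz), "
                f"got {self.lpf_cutoff}"
            )


def median_filter(series: np.ndarray, order: int = 3) -> np.ndarray:
    """Centered running median; edges handled by replicating the boundary sample.

    Length-preserving.  ``order`` must be odd and no longer than the series.
    """
    series = np.asarray(series, dtype=float)
    if order % 2 == 0 or order < 1:
        raise ValueError(f"median window must be odd >= 1, got {order}")
    if order > series.shape[0]:
        raise ValueError(f"median window {order} exceeds series length {series.shape[0]}")
    if order == 1:
        return series.copy()
    return ndimage.median_filter(series, size=order, mode="nearest")


def gravity_lowpass(
    series: np.ndarray, rate: float, config: FilterConfig | None = None
) -> np.ndarray:
    """Zero-phase Butterworth low-pass extracting the gravity component.

    Forward-backward application gives exactly unit DC gain and no phase
    distortion.  Raises if the cutoff reaches the Nyquist frequency.
    """
    config = config or FilterConfig()
    config.validate(rate)
    series = np.asarray(series, dtype=float)
    sos = signal.butter(
        config.lpf_order, config.lpf_cutoff, btype="low", fs=rate, output="sos"
    )
    # pad length generous relative to the 0.5 Hz time constant
    padlen = min(series.shape[0] - 1, int(3 * rate / config.lpf_cutoff))
    return signal.sosfiltfilt(sos, series, padlen=padlen)


def preprocess_session(session: Session, config: FilterConfig | None = None) -> Session:
    """Return a copy of the session with gravity-component streams attached.

    Per site and axis: median filter, then zero-phase low-pass.  The raw
    streams are retained alongside; gyroscope channels are median-filtered
    only (their slow component is not a gravity projection, so the 0.5 Hz
    low-pass does not apply).
    """
    problems = validate_session(session)
    if problems:
        raise ValueError("invalid session: " + "; ".join(problems))
    config = config or FilterConfig()
    rate = session.sampling_rate
    config.validate(rate)

    streams: dict[str, SensorStream] = {}
    for site in SITES:
        stream = session.streams[site]
        despiked = np.column_stack(
            [median_filter(stream.accel[:, j], config.median_order) for j in range(3)]
        )
        gravity = np.column_stack(
            [gravity_lowpass(despiked[:, j], rate, config) for j in range(3)]
        )
        gyro_smooth = None
        if stream.gyro is not None:
            gyro_smooth = np.column_stack(
                [median_filter(stream.gyro[:, j], config.median_order) for j in range(3)]
            )
        streams[site] = SensorStream(
            site=site,
            accel=stream.accel.copy(),
            gyro=None if stream.gyro is None else stream.gyro.copy(),
            sampling_rate=rate,
            gravity=gravity,
            gyro_smooth=gyro_smooth,
        )
    return Session(
        streams=streams,
        subject_id=session.subject_id,
        true_exercise=session.true_exercise,
        true_errors=session.true_errors,
        variant=session.variant,
        truth=session.truth,
    )


def motion_residual(stream: SensorStream) -> np.ndarray:
    """Raw-minus-gravity acceleration (the movement component), (n, 3) in g."""
    if stream.gravity is None:
        raise ValueError("gravity streams not computed; run preprocess_session first")
    return stream.accel - stream.gravity
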