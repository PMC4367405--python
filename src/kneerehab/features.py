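"""Per-repetition feature extraction for exercise-type classification.

Three feature families (26 values total):

* means of the raw acceleration per site and axis (9) -- gravity included,
  so static posture (standing vs. lying) is encoded; ``Mean_xT`` is the mean
  thigh x-axis acceleration;
* magnitudes of the first five FFT power-spectrum components of the
  gravity-removed long-axis (y) acceleration per site (15), named C1..C5
  (chest), T1..T5 (thigh), S1..S5 (shank); component numbering is 1-based,
  so T2 is the first non-DC bin;
* peak angles: highest thigh raising excursion (AngT) and shank excursion
  (AngS) of the repetition (2).

Variable-length activity windows are linearly resampled to a fixed length
(128 by default, about 3 s at 40 Hz) before the FFT so that spectral bins
are commensurate across repetitions and the features become invariant to
movement speed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import AngleMeasures
from .signal_io import Session

SITE_LETTER = {"chest": "C", "thigh": "T", "shank": "S"}

#: site blocks ordered by relevance to knee motion: the thigh drives every
#: exercise, the shank carries the knee angle, the chest only the trunk
SITE_ORDER = ("thigh", "shank", "chest")

#: canonical feature order: 9 means, 15 FFT magnitudes, 2 peak angles
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"Mean_{axis}{SITE_LETTER[site]}" for site in SITE_ORDER for axis in ("x", "y", "z")
) + tuple(
    f"{SITE_LETTER[site]}{k}" for site in SITE_ORDER for k in range(1, 6)
) + ("AngT", "AngS")


@dataclasses.dataclass
class FeatureParams:
    """fft_len: resample length before the FFT; fft_channel selects whether
    the spectrum is taken on the gravity-removed or raw y-axis signal."""

    fft_len: int = 128
    fft_channel: str = "gravity_removed_y"
    n_fft_components: int = 5


@dataclasses.dataclass
class FeatureVector:
    """Fixed-dimensionality (26) per-repetition feature vector."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.shape}"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def resample_segment(series: np.ndarray, target_len: int = 128) -> np.ndarray:
    """Linear interpolation onto ``target_len`` uniform points, endpoints kept."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("resample_segment needs at least 2 samples")
    if series.size == target_len:
        return series.copy()
    old = np.linspace(0.0, 1.0, series.size)
    new = np.linspace(0.0, 1.0, target_len)
    return np.interp(new, old, series)


def fft_power_features(segment: np.ndarray, k: int = 5) -> np.ndarray:
    """Magnitudes of the first ``k`` DFT components, normalized by length.

    With this normalization a constant signal c gives [|c|, 0, ...] and a
    unit cosine aligned to bin j gives 0.5 at component j+1; Parseval then
    reads sum_k |X_k/N|^2 = mean(x^2) over the full spectrum.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if k > n:
        raise ValueError(f"k={k} exceeds segment length {n}")
    spectrum = np.fft.fft(segment)
    return np.abs(spectrum[:k]) / n


def build_feature_vector(
    session: Session,
    repetition,
    angle_measures: AngleMeasures,
    params: FeatureParams | None = None,
) -> FeatureVector:
    """Assemble the 26-dimensional feature vector for one repetition.

    Means are taken over the raw (unfiltered) window; the FFT channel is the
    gravity-removed y-axis acceleration by default (``fft_channel='raw_y'``
    uses the raw signal instead).
    """
    params = params or FeatureParams()
    if hasattr(repetition, "start"):
        start, end = int(repetition.start), int(repetition.end)
    else:
        start, end = int(repetition[0]), int(repetition[1])
    if end - start < 2:
        raise ValueError("degenerate repetition: fewer than 2 samples")

    values: list[float] = []
    for site in SITE_ORDER:
        window = session.streams[site].accel[start:end]
        values.extend(np.mean(window, axis=0))

    for site in SITE_ORDER:
        stream = session.streams[site]
        raw_y = stream.accel[start:end, 1]
        if params.fft_channel == "gravity_removed_y":
            if stream.gravity is None:
                raise ValueError(
                    "gravity streams not computed; run preprocess_session or "
                    "use fft_channel='raw_y'"
                )
            channel = raw_y - stream.gravity[start:end, 1]
        elif params.fft_channel == "raw_y":
            channel = raw_y
        else:
            raise ValueError(f"unknown fft_channel '{params.fft_channel}'")
        resampled = resample_segment(channel, params.fft_len)
        values.extend(fft_power_features(resampled, params.n_fft_components))

    values.append(angle_measures.thigh_raise)
    values.append(angle_measures.shank_raise)
    return FeatureVector(values=np.asarray(values))
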