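"""Data model and file I/O for multi-site synchronized IMU recording sessions.

A recording session consists of one triaxial accelerometer (+ optional
gyroscope) stream per body site -- chest, thigh and shank of the working leg
-- sampled at a common fixed rate (40 Hz by default).  Acceleration is stored
in units of g (gravity normalized to 1.0) so that tilt-angle formulas need no
unit conversion; angular velocity is stored in deg/s.  Time is implicit:
sample index / sampling rate.

On-disk format: one CSV per site with header
``sample,ax_g,ay_g,az_g[,gx_dps,gy_dps,gz_dps]`` plus a small YAML manifest
holding the subject id, rate and per-site file names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

SITES = ("chest", "thigh", "shank")

ACCEL_COLUMNS = ("ax_g", "ay_g", "az_g")
GYRO_COLUMNS = ("gx_dps", "gy_dps", "gz_dps")


class SessionFormatError(ValueError):
    """Raised when session files or streams violate the format contract."""


@dataclasses.dataclass
class SensorStream:
    """One body site's synchronized IMU record.

    Parameters
    ----------
    site:
        One of ``chest``, ``thigh``, ``shank``.
    accel:
        ``(n, 3)`` acceleration in g (accelerometer output, i.e. specific
        force: a vertical axis pointing up reads +1 g at rest).
    gyro:
        Optional ``(n, 3)`` angular velocity in deg/s.
    sampling_rate:
        Samples per second (> 0).
    gravity:
        Optional ``(n, 3)`` gravity-component estimate filled in by
        :mod:`kneerehab.preprocess`; never serialized.
    gyro_smooth:
        Optional median-filtered gyro, filled in by preprocessing.
    """

    site: str
    accel: np.ndarray
    gyro: np.ndarray | None = None
    sampling_rate: float = 40.0
    gravity: np.ndarray | None = dataclasses.field(default=None, repr=False)
    gyro_smooth: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.accel.shape[0])

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate


@dataclasses.dataclass
class Session:
    """All three site streams of one recording, plus optional ground truth.

    ``true_exercise`` / ``true_errors`` carry simulator (or annotation)
    labels; ``variant`` and ``truth`` hold extra simulator ground truth
    (repetition boundaries, per-repetition angle measures) and are not part
    of the serialized CSV contract except for the labels in the manifest.
    """

    streams: dict[str, SensorStream]
    subject_id: str = "anonymous"
    true_exercise: str | None = None
    true_errors: frozenset[str] | None = None
    variant: str | None = None
    truth: dict | None = dataclasses.field(default=None, repr=False)

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.streams.values())).sampling_rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.streams.values())).n_samples

    @property
    def duration(self) -> float:
        return next(iter(self.streams.values())).duration

    @property
    def has_gyro(self) -> bool:
        return all(s.gyro is not None for s in self.streams.values())


def validate_session(session: Session) -> list[str]:
    """Return a list of invariant violations (empty iff the session is valid).

    Each violation names the offending field and, for per-sample problems,
    the first offending sample index.
    """
    problems: list[str] = []
    missing = [site for site in SITES if site not in session.streams]
    for site in missing:
        problems.append(f"missing stream for site '{site}'")
    present = [session.streams[s] for s in SITES if s in session.streams]
    if not present:
        return problems

    lengths = {s.site: s.n_samples for s in present}
    if len(set(lengths.values())) > 1:
        problems.append(f"ragged session: unequal stream lengths {lengths}")
    rates = {s.site: s.sampling_rate for s in present}
    if len(set(rates.values())) > 1:
        problems.append(f"sampling_rate mismatch between sites: {rates}")

    for stream in present:
        if stream.site not in SITES:
            problems.append(f"unknown site '{stream.site}'")
        if stream.sampling_rate <= 0:
            problems.append(f"{stream.site}: sampling_rate must be > 0")
        if stream.accel.ndim != 2 or stream.accel.shape[1] != 3:
            problems.append(f"{stream.site}: accel must have shape (n, 3)")
            continue
        if stream.n_samples == 0:
            problems.append(f"{stream.site}: accel is empty")
        bad = ~np.isfinite(stream.accel)
        if bad.any():
            idx = int(np.argwhere(bad.any(axis=1))[0, 0])
            problems.append(f"{stream.site}: non-finite accel at sample {idx}")
        if stream.gyro is not None:
            if stream.gyro.shape != stream.accel.shape:
                problems.append(
                    f"{stream.site}: gyro length {stream.gyro.shape[0]} != "
                    f"accel length {stream.n_samples}"
                )
            else:
                badg = ~np.isfinite(stream.gyro)
                if badg.any():
                    idx = int(np.argwhere(badg.any(axis=1))[0, 0])
                    problems.append(
                        f"{stream.site}: non-finite gyro at sample {idx}"
                    )
    return problems


def _require_valid(session: Session) -> None:
    problems = validate_session(session)
    if problems:
        raise SessionFormatError("; ".join(problems))


def _read_site_csv(path: Path, site: str, rate: float) -> SensorStream:
    if not Path(path).exists():
        raise SessionFormatError(f"missing file for site '{site}': {path}")
    df = pd.read_csv(path, dtype=str)
    needed = set(ACCEL_COLUMNS) - set(df.columns)
    if needed:
        raise SessionFormatError(f"{site}: missing columns {sorted(needed)}")
    has_gyro = all(c in df.columns for c in GYRO_COLUMNS)
    cols = list(ACCEL_COLUMNS) + (list(GYRO_COLUMNS) if has_gyro else [])
    numeric = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise SessionFormatError(
            f"{site}: non-numeric cell at data row {row} of {path}"
        )
    accel = numeric[list(ACCEL_COLUMNS)].to_numpy(dtype=float)
    gyro = numeric[list(GYRO_COLUMNS)].to_numpy(dtype=float) if has_gyro else None
    return SensorStream(site=site, accel=accel, gyro=gyro, sampling_rate=rate)


def read_session(
    paths: Mapping[str, str | Path] | str | Path,
    rate: float = 40.0,
    subject_id: str = "anonymous",
) -> Session:
    """Read a session from per-site CSV files or a YAML manifest.

    ``paths`` is either a mapping ``{site: csv_path}`` covering all three
    sites, or the path of a session manifest written by
    :func:`write_session`.  Row order is preserved verbatim.
    """
    if isinstance(paths, (str, Path)):
        return _read_manifest(Path(paths))
    streams = {}
    for site in SITES:
        if site not in paths:
            raise SessionFormatError(f"missing file for site '{site}'")
        streams[site] = _read_site_csv(Path(paths[site]), site, rate)
    session = Session(streams=streams, subject_id=subject_id)
    _require_valid(session)
    return session


def _read_manifest(manifest_path: Path) -> Session:
    if not manifest_path.exists():
        raise SessionFormatError(f"missing manifest: {manifest_path}")
    meta = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    paths = {site: base / meta["files"][site] for site in SITES if site in meta.get("files", {})}
    session = read_session(
        paths,
        rate=float(meta.get("rate_hz", 40.0)),
        subject_id=str(meta.get("subject_id", "anonymous")),
    )
    session.true_exercise = meta.get("exercise")
    errors = meta.get("errors")
    session.true_errors = frozenset(errors) if errors is not None else None
    session.variant = meta.get("variant")
    return session


def write_session(session: Session, directory: str | Path, stem: str = "session") -> Path:
    """Write one CSV per site plus ``<stem>_manifest.yaml``; returns the manifest path.

    Round-trip property: ``read_session(write_session(s))`` reproduces every
    numeric field to better than 1e-9.
    """
    _require_valid(session)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for site in SITES:
        stream = session.streams[site]
        n = stream.n_samples
        data: dict[str, np.ndarray] = {"sample": np.arange(n)}
        for j, col in enumerate(ACCEL_COLUMNS):
            data[col] = stream.accel[:, j]
        if stream.gyro is not None:
            for j, col in enumerate(GYRO_COLUMNS):
                data[col] = stream.gyro[:, j]
        name = f"{stem}_{site}.csv"
        pd.DataFrame(data).to_csv(directory / name, index=False, float_format="%.12g")
        files[site] = name
    meta: dict = {
        "subject_id": session.subject_id,
        "rate_hz": float(session.sampling_rate),
        "files": files,
    }
    if session.true_exercise is not None:
        meta["exercise"] = session.true_exercise
    if session.true_errors is not None:
        meta["errors"] = sorted(session.true_errors)
    if session.variant is not None:
        meta["variant"] = session.variant
    manifest = directory / f"{stem}_manifest.yaml"
    manifest.write_text(yaml.safe_dump(meta, sort_keys=False))
    return manifest
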