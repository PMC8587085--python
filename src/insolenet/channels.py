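"""Sensor channel layout and time-series containers for smart-insole recordings.

The instrumented shoe carries, per foot, four plantar-pressure sensors plus a
triaxial accelerometer and a triaxial gyroscope, giving 20 channels in total.
A fixed canonical channel ordering is used everywhere so that attention-weight
indices are stable across runs and reports can name sensors by id.

Axis convention (documented, not enforced): z is vertical, y is
anterior-posterior (direction of motion), x is medio-lateral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Anatomical location of each pressure site index.
PRESSURE_SITES = {
    1: "1st metatarsal head",
    2: "toe",
    3: "4th metatarsal head",
    4: "heel",
}

N_CHANNELS = 20


@dataclass(frozen=True)
class ChannelSpec:
    """One sensor channel: id, sensor family, shoe side and site/axis."""

    id: str
    family: str  # "pressure" | "accelerometer" | "gyroscope"
    side: str  # "L" | "R"
    site_or_axis: str  # "1".."4" for pressure, "x"/"y"/"z" for IMU


def canonical_channels() -> list[ChannelSpec]:
    """Return the 20 channel specs in canonical order.

    Order: pressure L1..L4, R1..R4, then accelerometer L(x,y,z), R(x,y,z),
    then gyroscope L(x,y,z), R(x,y,z).
    """
    specs: list[ChannelSpec] = []
    for side in "LR":
        for site in range(1, 5):
            specs.append(ChannelSpec(f"P_{side}{site}", "pressure", side, str(site)))
    for family, tag in (("accelerometer", "A"), ("gyroscope", "G")):
        for side in "LR":
            for axis in "xyz":
                specs.append(
                    ChannelSpec(f"{tag}_{side}{axis.upper()}", family, side, axis)
                )
    return specs


#: Canonical channel ids, in order.
CHANNEL_IDS: list[str] = [c.id for c in canonical_channels()]

#: Column indices (accelerometer + gyroscope) pooled per axis.
AXIS_GROUPS: dict[str, list[int]] = {
    axis: [i for i, c in enumerate(canonical_channels())
           if c.family != "pressure" and c.site_or_axis == axis]
    for axis in "xyz"
}

#: The four vertical-axis IMU channels (A_LZ, A_RZ, G_LZ, G_RZ).
Z_AXIS_IDS = [CHANNEL_IDS[i] for i in AXIS_GROUPS["z"]]


@dataclass
class SensorRecording:
    """A subject's multichannel shoe recording.

    signal has shape (n_samples, 20) with columns in canonical channel order;
    fs is the sampling rate in Hz (nominal 33.3); t0 the start time in seconds.
    """

    subject_id: str
    fs: float
    signal: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.ndim != 2 or self.signal.shape[1] != N_CHANNELS:
            raise ValueError(
                f"signal must be (n_samples, {N_CHANNELS}), got {self.signal.shape}"
            )
        if self.signal.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class PhysioStream:
    """Sparse, irregularly sampled HR (bpm) and EE (kcal/min) labels."""

    subject_id: str
    timestamps: np.ndarray
    hr: np.ndarray
    ee: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.ee = np.asarray(self.ee, dtype=float)
        if not (len(self.timestamps) == len(self.hr) == len(self.ee)):
            raise ValueError("timestamps, hr and ee must have equal length")
        diffs = np.diff(self.timestamps)
        if len(diffs) and (bad := np.flatnonzero(diffs <= 0)).size:
            raise ValueError(
                f"timestamps must be strictly increasing (violated at index {bad[0] + 1})"
            )
        if np.any(self.hr <= 0):
            raise ValueError("hr must be positive")
        if np.any(self.ee < 0):
            raise ValueError("ee must be non-negative")


# ---------------------------------------------------------------------------
# Delimited-text I/O. Recording files: header time_s,P_L1,...,G_RZ; label
# files: header time_s,hr_bpm,ee_kcal_min. UTF-8, "." decimal.
# ---------------------------------------------------------------------------

def _check_numeric(df: pd.DataFrame, path) -> None:
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0])
        raise ValueError(f"non-numeric or missing value at data row {row} of {path}")


def read_recording(path, subject_id: str | None = None) -> SensorRecording:
    """Read a recording file; columns are reordered to canonical order."""
    # round_trip parsing so write->read preserves doubles bit-for-bit
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"missing channel: time_s in {path}")
    for cid in CHANNEL_IDS:
        if cid not in df.columns:
            raise ValueError(f"missing channel: {cid} in {path}")
    df = df[["time_s"] + CHANNEL_IDS].apply(pd.to_numeric, errors="coerce")
    _check_numeric(df, path)
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 33.3
    if subject_id is None:
        subject_id = _stem(path)
    return SensorRecording(subject_id, fs, df[CHANNEL_IDS].to_numpy(), t0=float(t[0]))


def write_recording(rec: SensorRecording, path) -> None:
    df = pd.DataFrame(rec.signal, columns=CHANNEL_IDS)
    df.insert(0, "time_s", rec.times)
    # %.17g preserves doubles exactly, so write->read round-trips bit-for-bit
    df.to_csv(path, index=False, float_format="%.17g")


def read_labels(path, subject_id: str | None = None) -> PhysioStream:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "hr_bpm", "ee_kcal_min"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col} in {path}")
    df = df[["time_s", "hr_bpm", "ee_kcal_min"]].apply(pd.to_numeric, errors="coerce")
    _check_numeric(df, path)
    if subject_id is None:
        subject_id = _stem(path)
    return PhysioStream(
        subject_id,
        df["time_s"].to_numpy(),
        df["hr_bpm"].to_numpy(),
        df["ee_kcal_min"].to_numpy(),
    )


def write_labels(stream: PhysioStream, path) -> None:
    pd.DataFrame(
        {"time_s": stream.timestamps, "hr_bpm": stream.hr, "ee_kcal_min": stream.ee}
    ).to_csv(path, index=False, float_format="%.17g")


def _stem(path) -> str:
    import os

    name = os.path.basename(str(path))
    return name.rsplit(".", 1)[0]
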