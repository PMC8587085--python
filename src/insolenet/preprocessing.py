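"""Label resampling, channel standardization and overlapping-window extraction.

Sparse HR/EE labels (recorded every ~2-5 s) are linearly interpolated onto the
33.3 Hz sensor clock, channels are z-scored with statistics fitted on training
subjects only, and the continuous recording is cut into 10-s windows advanced
by 1 s; each window's label is the mean of the interpolated label over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .channels import CHANNEL_IDS, N_CHANNELS, PhysioStream, SensorRecording


@dataclass
class WindowedSample:
    """One model input window: (t x 20) signal slab plus its averaged labels."""

    s_in: np.ndarray  # (t, 20)
    label_hr: float
    label_ee: float
    subject_id: str
    start_s: float


@dataclass
class StandardizationStats:
    """Per-channel mean/std (population convention) and their provenance."""

    mean: np.ndarray  # (20,)
    std: np.ndarray  # (20,)
    fitted_on: list[str]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            bad = CHANNEL_IDS[int(np.flatnonzero(self.std <= 0)[0])]
            raise ValueError(f"non-positive std for channel {bad}")


def interpolate_labels(
    stream: PhysioStream, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear HR/EE values on ``grid`` (seconds).

    Exact at label timestamps. Grid points outside the label span are clamped
    to the nearest end value, with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (
        grid.min() < stream.timestamps[0] or grid.max() > stream.timestamps[-1]
    ):
        warnings.warn(
            "label grid extends outside the label time span; clamping to end values",
            stacklevel=2,
        )
    hr = np.interp(grid, stream.timestamps, stream.hr)
    ee = np.interp(grid, stream.timestamps, stream.ee)
    return hr, ee


def fit_standardizer(recordings: list[SensorRecording]) -> StandardizationStats:
    """Pooled per-channel mean/std (ddof=0) over all samples of all recordings."""
    if not recordings:
        raise ValueError("need at least one recording")
    pooled = np.concatenate([r.signal for r in recordings], axis=0)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)  # population convention
    if np.any(std == 0):
        bad = CHANNEL_IDS[int(np.flatnonzero(std == 0)[0])]
        raise ValueError(f"zero-variance channel: {bad}")
    return StandardizationStats(mean, std, [r.subject_id for r in recordings])


def apply_standardizer(
    recording: SensorRecording, stats: StandardizationStats
) -> SensorRecording:
    """Return a copy of ``recording`` with (x - mean)/std applied per channel."""
    return SensorRecording(
        recording.subject_id,
        recording.fs,
        (recording.signal - stats.mean) / stats.std,
        t0=recording.t0,
    )


def extract_windows(
    recording: SensorRecording,
    stream: PhysioStream,
    window_s: float = 10.0,
    hop_s: float = 1.0,
) -> list[WindowedSample]:
    """Cut overlapping windows and average the interpolated labels over each.

    Window length is round(window_s * fs) samples and the hop round(hop_s * fs)
    samples (333 and 33 at the nominal 33.3 Hz); the window count is
    floor((n_samples - win) / hop) + 1. A recording shorter than one window
    yields an empty list with a warning.
    """
    win = int(round(window_s * recording.fs))
    hop = int(round(hop_s * recording.fs))
    if win < 1 or hop < 1:
        raise ValueError("window and hop must be at least one sample")
    n = recording.n_samples
    if n < win:
        warnings.warn(
            f"recording {recording.subject_id} shorter than one window; no samples",
            stacklevel=2,
        )
        return []
    hr_grid, ee_grid = interpolate_labels(stream, recording.times)
    out: list[WindowedSample] = []
    for k in range((n - win) // hop + 1):
        a = k * hop
        out.append(
            WindowedSample(
                s_in=recording.signal[a : a + win],
                label_hr=float(hr_grid[a : a + win].mean()),
                label_ee=float(ee_grid[a : a + win].mean()),
                subject_id=recording.subject_id,
                start_s=recording.t0 + a / recording.fs,
            )
        )
    return out


def n_windows(duration_s: float, window_s: float, hop_s: float) -> int:
    """Closed-form window count floor((D - W) / H) + 1 (0 when D < W)."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / hop_s + 1e-9)) + 1


def save_windows(windows: list[WindowedSample], path) -> None:
    """Persist a windowed dataset: stacked arrays plus a sidecar manifest.

    The .npz holds the signal stack and labels; the companion .json manifest
    records subject ids and window start times so training is restart-safe.
    """
    import json
    from pathlib import Path

    path = Path(path)
    x = np.stack([w.s_in for w in windows])
    np.savez(
        path,
        s_in=x,
        label_hr=np.array([w.label_hr for w in windows]),
        label_ee=np.array([w.label_ee for w in windows]),
    )
    manifest = {
        "n_windows": len(windows),
        "window_shape": list(x.shape[1:]),
        "subject_ids": [w.subject_id for w in windows],
        "start_s": [w.start_s for w in windows],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest))


def load_windows(path) -> list[WindowedSample]:
    """Inverse of save_windows."""
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        return [
            WindowedSample(
                s_in=data["s_in"][i],
                label_hr=float(data["label_hr"][i]),
                label_ee=float(data["label_ee"][i]),
                subject_id=manifest["subject_ids"][i],
                start_s=float(manifest["start_s"][i]),
            )
            for i in range(manifest["n_windows"])
        ]


def build_loso_folds(subject_ids: list[str]) -> list[tuple[list[str], str]]:
    """Leave-one-subject-out folds: one (train_ids, test_id) pair per subject."""
    ids = list(subject_ids)
    if len(ids) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    return [([s for s in ids if s != held], held) for held in ids]


def stack_windows(windows: list[WindowedSample], target: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, t, 20) inputs and an (n,) label vector."""
    if target not in ("hr", "ee"):
        raise ValueError("target must be 'hr' or 'ee'")
    x = np.stack([w.s_in for w in windows]) if windows else np.zeros((0, 0, N_CHANNELS))
    y = np.array(
        [w.label_hr if target == "hr" else w.label_ee for w in windows], dtype=float
    )
    return x, y
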