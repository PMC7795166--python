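"""Core data model and signal plumbing.

Holds the timestamped 6-channel inertial recording (:class:`ImuSeries`),
the behaviour/posture interval annotation (:class:`LabelTrack`) and the
fixed-length analysis window (:class:`Window`), together with the signal
operations every downstream module builds on: Euclidean magnitude,
annotation time-offset correction, window discretisation with overlap,
and stride-based down-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ethogram

#: Down-sampling targets supported for a 100 Hz recording, with strides.
DOWNSAMPLE_STRIDES = {50: 2, 20: 5, 10: 10, 4: 25}


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of a triaxial signal.

    Removes the dependence on sensor mounting orientation: the result is
    invariant under axis permutation and sign flips.
    """
    x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
    if not (x.shape == y.shape == z.shape):
        raise ValueError(
            f"axis length mismatch: {x.shape} vs {y.shape} vs {z.shape}"
        )
    # dtype follows the input (float32 recordings stay float32).
    return np.sqrt(x * x + y * y + z * z)


@dataclass
class ImuSeries:
    """Uniformly sampled 6-channel inertial recording for one animal.

    Parameters
    ----------
    animal_id : str
        Identifier of the recording / animal.
    sample_rate : float
        Samples per second (nominal 100 Hz collar sensor).
    timestamps : ndarray of float
        Seconds, strictly increasing with spacing 1/sample_rate.
    accel : ndarray, shape (n, 3)
        Accelerometer axes x, y, z in g.
    gyro : ndarray, shape (n, 3)
        Gyroscope axes x, y, z in degrees/second.
    """

    animal_id: str
    sample_rate: float
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.accel = np.atleast_2d(np.asarray(self.accel))
        self.gyro = np.atleast_2d(np.asarray(self.gyro))
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                "accel and gyro must have shape (n, 3) matching timestamps; "
                f"got {self.accel.shape}, {self.gyro.shape} for n={n}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    "non-uniform timestamps: expected fixed spacing "
                    f"{1.0 / self.sample_rate:g} s"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def accel_magnitude(self) -> np.ndarray:
        return magnitude(self.accel[:, 0], self.accel[:, 1], self.accel[:, 2])

    @property
    def gyro_magnitude(self) -> np.ndarray:
        return magnitude(self.gyro[:, 0], self.gyro[:, 1], self.gyro[:, 2])


@dataclass
class LabelTrack:
    """Ordered, non-overlapping labelled time intervals for one animal.

    ``kind`` selects the permitted vocabulary: ``"behaviour"`` (7-state
    ethogram) or ``"posture"`` (lying/standing).
    """

    animal_id: str
    intervals: list[tuple[float, float, str]]
    kind: str = "behaviour"

    def __post_init__(self) -> None:
        if self.kind not in ("behaviour", "posture"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        allowed = ethogram.BEHAVIOURS if self.kind == "behaviour" else ethogram.POSTURES
        prev_stop = -np.inf
        for start, stop, label in self.intervals:
            if stop <= start:
                raise ValueError(f"interval ({start}, {stop}) has stop <= start")
            if start < prev_stop:
                raise ValueError("intervals overlap or are out of order")
            if label not in allowed:
                raise ValueError(f"label {label!r} not in the {self.kind} ethogram")
            prev_stop = stop

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def total_time(self, label: str) -> float:
        return sum(b - a for a, b, lab in self.intervals if lab == label)


def apply_time_offset(track: LabelTrack, offset_s: float) -> LabelTrack:
    """Shift every interval by ``offset_s`` seconds.

    Used to correct video/sensor timestamp desynchronisation after visual
    alignment of the accelerometer magnitude with the footage.
    """
    shifted = [(a + offset_s, b + offset_s, lab) for a, b, lab in track.intervals]
    return LabelTrack(track.animal_id, shifted, track.kind)


@dataclass
class Window:
    """One fixed-length analysis window over the magnitude streams.

    ``accel_mag``/``gyro_mag`` are views into the parent series' magnitude
    arrays; ``label`` is the behaviour (or posture) covering the majority
    of the window span, or ``None`` when no single state does.
    """

    animal_id: str
    start_s: float
    length_s: float
    sample_rate: float
    accel_mag: np.ndarray
    gyro_mag: np.ndarray
    label: str | None = None

    def __len__(self) -> int:
        return len(self.accel_mag)


def window_count(n_samples: int, window_samples: int, hop_samples: int) -> int:
    """Closed-form number of overlapping windows in a series of n samples."""
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // hop_samples + 1


def _window_labels(
    track: LabelTrack | None,
    starts_s: np.ndarray,
    window_s: float,
    min_coverage: float,
) -> list[str | None]:
    """Majority-coverage label per window.

    A window receives label ``b`` iff intervals of ``b`` cover strictly more
    than ``min_coverage`` of the window's time span; otherwise it stays
    unlabelled (excluded from classifier training, retained as non-target
    material for quantification).
    """
    labels: list[str | None] = [None] * len(starts_s)
    if track is None or not track.intervals:
        return labels
    stops_s = starts_s + window_s
    coverage: dict[str, np.ndarray] = {}
    for a, b, lab in track.intervals:
        ov = np.clip(np.minimum(stops_s, b) - np.maximum(starts_s, a), 0.0, None)
        if lab in coverage:
            coverage[lab] += ov
        else:
            coverage[lab] = ov
    threshold = min_coverage * window_s
    for lab, cov in coverage.items():
        for i in np.nonzero(cov > threshold)[0]:
            labels[int(i)] = lab
    return labels


def discretize(
    series: ImuSeries,
    track: LabelTrack | None = None,
    window_s: float = 3.0,
    overlap_frac: float = 0.5,
    min_label_coverage: float = 0.5,
) -> list[Window]:
    """Slice a recording into equal-length windows with fractional overlap.

    Windows of ``window_s`` seconds start every ``window_s * (1 -
    overlap_frac)`` seconds (hop = half a window at the default 50%
    overlap).  A series shorter than one window yields an empty list.
    """
    if not (1.0 <= window_s <= 10.0):
        raise ValueError("window_s must lie in [1, 10] seconds")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must lie in [0, 1)")
    w = int(round(window_s * series.sample_rate))
    h = int(round(w * (1.0 - overlap_frac)))
    if h < 1:
        raise ValueError("hop of less than one sample")
    n = len(series)
    count = window_count(n, w, h)
    if count == 0:
        return []
    start_idx = np.arange(count) * h
    t0 = series.timestamps[0]
    starts_s = t0 + start_idx / series.sample_rate
    labels = _window_labels(track, starts_s, window_s, min_label_coverage)
    acc_mag = series.accel_magnitude
    gyr_mag = series.gyro_magnitude
    return [
        Window(
            animal_id=series.animal_id,
            start_s=float(starts_s[i]),
            length_s=window_s,
            sample_rate=series.sample_rate,
            accel_mag=acc_mag[s : s + w],
            gyro_mag=gyr_mag[s : s + w],
            label=labels[i],
        )
        for i, s in enumerate(start_idx)
    ]


def downsample(series: ImuSeries, target_hz: int) -> ImuSeries:
    """Reduce a 100 Hz recording to 50/20/10/4 Hz by stride selection.

    Keeps every d-th sample starting from the first (d = 100/target); the
    output is an exact subsequence of the input, no anti-alias filtering —
    emulating a sensor that simply records less often.
    """
    if series.sample_rate != 100:
        raise ValueError("downsample expects a 100 Hz input series")
    if target_hz not in DOWNSAMPLE_STRIDES:
        raise ValueError(
            f"unsupported target {target_hz} Hz; choose one of "
            f"{sorted(DOWNSAMPLE_STRIDES)}"
        )
    d = DOWNSAMPLE_STRIDES[target_hz]
    return ImuSeries(
        animal_id=series.animal_id,
        sample_rate=float(target_hz),
        timestamps=series.timestamps[::d].copy(),
        accel=series.accel[::d].copy(),
        gyro=series.gyro[::d].copy(),
    )


# ---------------------------------------------------------------------------
# CSV dialects shared with the simulator and the CLI.

SENSOR_COLUMNS = ["timestamp_s", "ax", "ay", "az", "gx", "gy", "gz"]
LABEL_COLUMNS = ["start_s", "stop_s", "behaviour"]


def write_sensor_csv(series: ImuSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.timestamps, series.accel, series.gyro]),
        columns=SENSOR_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_sensor_csv(path: str | Path, animal_id: str, sample_rate: float = 100.0) -> ImuSeries:
    df = pd.read_csv(path)
    missing = set(SENSOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sensor CSV missing columns {sorted(missing)}")
    return ImuSeries(
        animal_id=animal_id,
        sample_rate=sample_rate,
        timestamps=df["timestamp_s"].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
    )


def write_label_csv(track: LabelTrack, path: str | Path) -> None:
    pd.DataFrame(track.intervals, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_label_csv(path: str | Path, animal_id: str, kind: str = "behaviour") -> LabelTrack:
    df = pd.read_csv(path)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns {sorted(missing)}")
    intervals = [
        (float(r.start_s), float(r.stop_s), str(r.behaviour)) for r in df.itertuples()
    ]
    return LabelTrack(animal_id, intervals, kind)
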