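"""Per-window feature extraction from the magnitude streams.

Each analysis window yields a 44-value characteristic vector computed from
four streams — the accelerometer magnitude, the gyroscope magnitude, and
the first difference of each — with 11 statistics per stream:

time domain (6)
    mean, minimum, maximum, excess kurtosis, zero-crossing count of the
    mean-centred signal, and signal area (rectangular integral of the
    rectified signal, units value*seconds);
frequency domain (5), on the one-sided unwindowed periodogram with the
DC bin removed
    normalised spectral entropy, spectrum minimum, first quartile of the
    unit-sum-normalised spectrum, mean-crossing count of the spectrum,
    and spectrum area (total power times bin width).

The catalogue is an explicit ordered object so that the feature set can be
swapped by configuration; the default construction above is checked to
contain exactly 44 uniquely named entries, 22 per modality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .signal_core import Window

MODALITIES = ("accel", "gyro")
STREAMS = ("raw", "diff")
TIME_STATISTICS = ("mean", "min", "max", "kurtosis", "zero_crossings", "signal_area")
FREQ_STATISTICS = ("spectral_entropy", "spec_min", "spec_q1", "spec_mean_crossings", "spec_area")


@dataclass(frozen=True)
class FeatureDescriptor:
    modality: str   # accel | gyro
    stream: str     # raw | diff (first difference)
    domain: str     # time | frequency
    statistic: str

    @property
    def name(self) -> str:
        return f"{self.modality}_{self.stream}_{self.statistic}"


class FeatureCatalogue:
    """Ordered, validated list of feature descriptors."""

    def __init__(self, descriptors: Sequence[FeatureDescriptor], expected_size: int | None = 44):
        names = [d.name for d in descriptors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalogue")
        if expected_size is not None and len(descriptors) != expected_size:
            raise ValueError(
                f"catalogue holds {len(descriptors)} features, expected {expected_size}"
            )
        per_modality = {m: sum(d.modality == m for d in descriptors) for m in MODALITIES}
        if expected_size == 44 and any(v != 22 for v in per_modality.values()):
            raise ValueError(f"modalities must contribute 22 features each, got {per_modality}")
        self.descriptors = list(descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def to_yaml(self, path: str | Path) -> None:
        rows = [
            {"modality": d.modality, "stream": d.stream, "domain": d.domain,
             "statistic": d.statistic}
            for d in self.descriptors
        ]
        Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, expected_size: int | None = 44) -> "FeatureCatalogue":
        rows = yaml.safe_load(Path(path).read_text())
        return cls([FeatureDescriptor(**r) for r in rows], expected_size=expected_size)


def default_catalogue() -> FeatureCatalogue:
    """The default 44-feature catalogue: 4 streams x 11 statistics."""
    descriptors = []
    for modality in MODALITIES:
        for stream in STREAMS:
            for stat in TIME_STATISTICS:
                descriptors.append(FeatureDescriptor(modality, stream, "time", stat))
            for stat in FREQ_STATISTICS:
                descriptors.append(FeatureDescriptor(modality, stream, "frequency", stat))
    return FeatureCatalogue(descriptors)


# ---------------------------------------------------------------------------
# Primitive statistics (1-D reference forms).


def first_difference(signal: np.ndarray) -> np.ndarray:
    """out[i] = s[i+1] - s[i]; length n-1."""
    signal = np.asarray(signal, float)
    if signal.size < 2:
        raise ValueError("first_difference needs at least 2 samples")
    return np.diff(signal)


def zero_crossings(signal: np.ndarray) -> int:
    """Sign changes of the mean-centred signal between consecutive samples.

    Samples exactly on the mean carry sign zero and do not themselves
    produce a crossing (strict sign-product rule).
    """
    signal = np.asarray(signal, float)
    if signal.size < 2:
        raise ValueError("zero_crossings needs at least 2 samples")
    d = signal - signal.mean()
    return int(np.count_nonzero(d[:-1] * d[1:] < 0))


def signal_area(signal: np.ndarray, sample_rate: float) -> float:
    """Rectangular integral of the rectified signal: sum |s| / sample_rate."""
    signal = np.asarray(signal, float)
    if signal.size < 1:
        raise ValueError("signal_area needs at least 1 sample")
    return float(np.abs(signal).sum() / sample_rate)


def periodogram(signal: np.ndarray) -> np.ndarray:
    """One-sided unwindowed power spectrum with the DC bin removed."""
    signal = np.asarray(signal, float)
    if signal.size < 4:
        raise ValueError("periodogram needs at least 4 samples")
    spec = np.abs(np.fft.rfft(signal)) ** 2
    return spec[1:]


def spectral_entropy(signal: np.ndarray, sample_rate: float | None = None) -> float:
    """Shannon entropy of the unit-sum periodogram, scaled to [0, 1].

    1 for a flat (white) spectrum, near 0 for a single-bin tone; defined
    as 0 for a zero-power (constant) signal.
    """
    p = periodogram(signal)
    total = p.sum()
    if total <= 0:
        return 0.0
    q = p / total
    nz = q[q > 0]
    h = float(-(nz * np.log(nz)).sum())
    norm = np.log(len(p))
    return h / norm if norm > 0 else 0.0


# ---------------------------------------------------------------------------
# Vectorised batch computation over a (n_windows, n_samples) matrix.


def _batch_kurtosis(mat: np.ndarray) -> np.ndarray:
    # Excess kurtosis m4/m2^2 - 3; zero-variance rows are defined as 0 so
    # that perfectly quiet windows remain usable.
    centred = mat - mat.mean(axis=1, keepdims=True)
    np.multiply(centred, centred, out=centred)  # centred -> squared deviations
    m2 = centred.mean(axis=1, dtype=np.float64)
    np.multiply(centred, centred, out=centred)  # -> 4th-power deviations
    m4 = centred.mean(axis=1, dtype=np.float64)
    out = np.zeros(len(mat))
    ok = m2 > 0
    out[ok] = m4[ok] / (m2[ok] ** 2) - 3.0
    return out


def _batch_zero_crossings(mat: np.ndarray, center: bool = True) -> np.ndarray:
    d = mat - mat.mean(axis=1, keepdims=True) if center else mat
    return np.count_nonzero(d[:, :-1] * d[:, 1:] < 0, axis=1).astype(float)


def _batch_stream_features(mat: np.ndarray, sample_rate: float) -> dict[str, np.ndarray]:
    """All 11 statistics for one stream, vectorised over windows (rows)."""
    n_samp = mat.shape[1]
    feats: dict[str, np.ndarray] = {}
    feats["mean"] = mat.mean(axis=1)
    feats["min"] = mat.min(axis=1)
    feats["max"] = mat.max(axis=1)
    feats["kurtosis"] = _batch_kurtosis(mat)
    feats["zero_crossings"] = _batch_zero_crossings(mat)
    feats["signal_area"] = np.abs(mat).sum(axis=1) / sample_rate

    spec = np.abs(np.fft.rfft(mat, axis=1)) ** 2
    spec = spec[:, 1:]  # drop DC
    n_bins = spec.shape[1]
    total = spec.sum(axis=1)
    ok = total > 0
    q = np.zeros_like(spec)
    q[ok] = spec[ok] / total[ok, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        logq = np.where(q > 0, np.log(q), 0.0)
    h = -(q * logq).sum(axis=1)
    norm = np.log(n_bins) if n_bins > 1 else 1.0
    feats["spectral_entropy"] = np.where(ok, h / norm, 0.0)
    feats["spec_min"] = spec.min(axis=1)
    feats["spec_q1"] = np.quantile(q, 0.25, axis=1)
    feats["spec_mean_crossings"] = _batch_zero_crossings(spec)
    feats["spec_area"] = total * (sample_rate / n_samp)
    return feats


def _stream_matrix(mat: np.ndarray, stream: str) -> np.ndarray:
    return np.diff(mat, axis=1) if stream == "diff" else mat


def extract_feature_matrix(
    windows: Sequence[Window], catalogue: FeatureCatalogue | None = None
) -> pd.DataFrame:
    """Feature vectors for a batch of equal-length windows.

    Returns one row per window, columns in catalogue order, plus the
    bookkeeping columns ``animal_id``, ``start_s``, ``window_s`` and
    ``behaviour`` (the window's majority label, NaN when unlabelled).
    """
    if catalogue is None:
        catalogue = default_catalogue()
    if not windows:
        return pd.DataFrame(
            columns=["animal_id", "start_s", "window_s", "behaviour"] + catalogue.names
        )
    n_samp = len(windows[0])
    if any(len(w) != n_samp for w in windows):
        raise ValueError("all windows in a batch must have equal length")
    min_needed = 5  # diff-stream periodogram needs >= 4 samples
    if n_samp < min_needed:
        raise ValueError(
            f"windows of {n_samp} samples are too short: the difference-stream "
            f"frequency features (e.g. {catalogue.names[-1]}) need at least "
            f"{min_needed} samples"
        )
    sample_rate = windows[0].sample_rate
    mats = {
        "accel": np.stack([w.accel_mag for w in windows]),
        "gyro": np.stack([w.gyro_mag for w in windows]),
    }
    stream_feats: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for modality in MODALITIES:
        for stream in STREAMS:
            stream_feats[(modality, stream)] = _batch_stream_features(
                _stream_matrix(mats[modality], stream), sample_rate
            )
    data = {
        "animal_id": [w.animal_id for w in windows],
        "start_s": [w.start_s for w in windows],
        "window_s": [w.length_s for w in windows],
        "behaviour": [w.label for w in windows],
    }
    for d in catalogue:
        data[d.name] = stream_feats[(d.modality, d.stream)][d.statistic]
    return pd.DataFrame(data)


def extract_features(window: Window, catalogue: FeatureCatalogue | None = None) -> pd.Series:
    """The 44-value characteristic vector of a single window, name-keyed."""
    if catalogue is None:
        catalogue = default_catalogue()
    frame = extract_feature_matrix([window], catalogue)
    return frame.iloc[0][catalogue.names]


def build_feature_frame(
    dataset: Iterable[tuple],
    window_s: float = 3.0,
    overlap_frac: float = 0.5,
    catalogue: FeatureCatalogue | None = None,
) -> pd.DataFrame:
    """Windowed feature table for a multi-animal dataset.

    ``dataset`` yields (ImuSeries, LabelTrack-or-None) pairs; each recording
    is discretised and featurised independently and the rows concatenated.
    """
    from .signal_core import discretize

    if catalogue is None:
        catalogue = default_catalogue()
    frames = []
    for series, track in dataset:
        windows = discretize(series, track, window_s=window_s, overlap_frac=overlap_frac)
        if windows:
            frames.append(extract_feature_matrix(windows, catalogue))
    if not frames:
        return pd.DataFrame(
            columns=["animal_id", "start_s", "window_s", "behaviour"] + catalogue.names
        )
    return pd.concat(frames, ignore_index=True)
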