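"""Dual Frequency Head Map (DFHM) features.

Cleaned EEG is cut into 1-s segments overlapping by 0.5 s; an FFT
periodogram gives per-electrode band powers (theta 4–8 Hz, alpha
8–12 Hz, half-open intervals so 8 Hz belongs to alpha only); powers are
z-scored against per-subject baseline statistics from the first minute
of the recording; and the z-scores of frontal theta plus parietal alpha
form one DFHM vector per segment.

Band power is the *sum* of periodogram bins in the band, normalized so a
unit-amplitude sinusoid at an on-grid frequency contributes exactly 1/2
(amplitude²/2, Parseval). Z-scoring makes downstream results invariant
to the sum-vs-mean choice under a fixed segment grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .montage import Montage
from .preprocess import require_preprocessed
from .recording import EEGRecording

__all__ = [
    "BandDefinition",
    "THETA",
    "ALPHA",
    "SegmentGrid",
    "BaselineStats",
    "DFHM",
    "segment",
    "band_power",
    "compute_baseline",
    "build_dfhm",
    "extract_dfhm_series",
    "DFHMExtractor",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band requires low < high")


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)


@dataclass(frozen=True)
class SegmentGrid:
    """Sliding segment grid: ``length`` seconds stepping by ``step``."""

    length: float = 1.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.length:
            raise ValueError("need 0 < step <= length")

    def n_segments(self, duration: float) -> int:
        if duration < self.length:
            return 0
        return int(np.floor((duration - self.length) / self.step + 1e-9)) + 1

    def starts(self, duration: float) -> np.ndarray:
        return np.arange(self.n_segments(duration)) * self.step


def segment(recording: EEGRecording, grid: SegmentGrid = SegmentGrid()):
    """Cut a recording into overlapping segments.

    Returns ``(times, data)`` where ``data`` has shape (n_segments,
    n_channels, segment_samples); only windows that fit entirely inside
    the recording are produced.
    """
    n = grid.n_segments(recording.duration)
    if n == 0:
        raise ValueError(
            f"recording of {recording.duration} s shorter than one "
            f"{grid.length} s segment"
        )
    fs = recording.sample_rate
    seg_len = int(round(grid.length * fs))
    starts = grid.starts(recording.duration)
    data = np.stack(
        [recording.samples[:, int(round(t * fs)):int(round(t * fs)) + seg_len]
         for t in starts]
    )
    return starts, data


def band_power(
    seg: np.ndarray,
    band: BandDefinition,
    sample_rate: float,
    taper: str = "rect",
) -> np.ndarray:
    """Periodogram band power (µV²) per channel of one segment.

    ``seg`` is (n_channels, n_samples) or 1-D. Power in each one-sided bin
    is 2|X_k|²/N² (DC and Nyquist unscaled), summed over bins with
    ``band.low <= f < band.high``; summing over a full partition of the
    spectrum recovers the segment's mean square (Parseval). ``taper`` is
    ``"rect"`` (default, plain FFT) or ``"hann"``.
    """
    x = np.atleast_2d(np.asarray(seg, dtype=float))
    n = x.shape[1]
    if band.high > sample_rate / 2.0:
        raise ValueError(f"band {band.name} exceeds Nyquist ({sample_rate / 2} Hz)")
    if n < sample_rate / (band.high - band.low):
        raise ValueError("segment too short to resolve the band")
    if taper == "hann":
        w = np.hanning(n)
        x = x * w[None, :]
        norm = (w**2).mean()
    elif taper == "rect":
        norm = 1.0
    else:
        raise ValueError(f"unknown taper {taper!r}")
    X = np.fft.rfft(x, axis=1)
    p = (np.abs(X) ** 2) * (2.0 / n**2)
    p[:, 0] /= 2.0
    if n % 2 == 0:
        p[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    mask = (freqs >= band.low) & (freqs < band.high)
    out = p[:, mask].sum(axis=1) / norm
    return out if np.asarray(seg).ndim > 1 else out[0]


SD_FLOOR = 1e-12  # µV², guards degenerate (constant-power) baselines


@dataclass
class BaselineStats:
    """Per-electrode, per-band mean/SD of band power over the baseline window."""

    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    window: float
    n_segments: int
    floored: dict[str, np.ndarray] = field(default_factory=dict)  # band → bool mask

    def bands(self) -> tuple[str, ...]:
        return tuple(self.mean)


def compute_baseline(
    recording: EEGRecording,
    grid: SegmentGrid = SegmentGrid(),
    window: float = 60.0,
    bands: tuple[BandDefinition, ...] = (THETA, ALPHA),
    taper: str = "rect",
) -> BaselineStats:
    """Baseline band-power statistics from the first ``window`` seconds.

    Only segments lying entirely inside [0, window) contribute. A recording
    shorter than the window raises — the baseline is never silently
    shortened. SDs below :data:`SD_FLOOR` are floored and flagged.
    """
    if recording.duration < window:
        raise ValueError(
            f"recording ({recording.duration} s) shorter than baseline "
            f"window ({window} s)"
        )
    starts, data = segment(recording, grid)
    inside = starts + grid.length <= window + 1e-9
    if not inside.any():
        raise ValueError("no complete segment inside the baseline window")
    data = data[inside]
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    floored: dict[str, np.ndarray] = {}
    for band in bands:
        powers = np.stack(
            [band_power(s, band, recording.sample_rate, taper) for s in data]
        )  # (n_seg, n_ch)
        mean[band.name] = powers.mean(axis=0)
        s = powers.std(axis=0, ddof=1) if len(powers) > 1 else np.zeros(powers.shape[1])
        mask = s < SD_FLOOR
        if mask.any():
            warnings.warn(
                f"baseline SD floor engaged for band {band.name!r} on "
                f"{int(mask.sum())} electrode(s)",
                stacklevel=2,
            )
        floored[band.name] = mask
        sd[band.name] = np.where(mask, SD_FLOOR, s)
    return BaselineStats(
        mean=mean, sd=sd, window=window, n_segments=int(inside.sum()), floored=floored
    )


@dataclass(frozen=True)
class DFHM:
    """One segment's feature vector: z-scored frontal theta and parietal alpha."""

    z_frontal_theta: np.ndarray
    z_parietal_alpha: np.ndarray
    segment_time: float

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.z_frontal_theta, self.z_parietal_alpha])

    @property
    def dim(self) -> int:
        return self.z_frontal_theta.size + self.z_parietal_alpha.size


def build_dfhm(
    powers: dict[str, np.ndarray],
    baseline: BaselineStats,
    montage: Montage,
    segment_time: float = 0.0,
) -> DFHM:
    """Assemble one DFHM from full-montage band powers.

    ``powers`` maps band name → per-channel power over the whole montage;
    each designated electrode's entry is (power − baseline mean)/baseline SD
    for its band.
    """
    for band in ("theta", "alpha"):
        if band not in powers or band not in baseline.mean:
            raise KeyError(f"band {band!r} missing from powers or baseline")
    fi = montage.indices(montage.frontal_set)
    pi = montage.indices(montage.parietal_set)
    z_theta = (powers["theta"][fi] - baseline.mean["theta"][fi]) / baseline.sd["theta"][fi]
    z_alpha = (powers["alpha"][pi] - baseline.mean["alpha"][pi]) / baseline.sd["alpha"][pi]
    if not (np.isfinite(z_theta).all() and np.isfinite(z_alpha).all()):
        raise ValueError("non-finite DFHM entries")
    return DFHM(z_frontal_theta=z_theta, z_parietal_alpha=z_alpha, segment_time=segment_time)


def extract_dfhm_series(
    recording: EEGRecording,
    baseline: BaselineStats,
    grid: SegmentGrid = SegmentGrid(),
    taper: str = "rect",
    enforce_preprocessing: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """DFHM vectors for every segment of a recording.

    Returns ``(times, X)`` with ``X`` of shape (n_segments, n_frontal +
    n_parietal). Each row uses only samples in [t, t + length) — no
    lookahead. With ``enforce_preprocessing`` the provenance must show the
    canonical conditioning chain.
    """
    if enforce_preprocessing:
        require_preprocessed(recording)
    m = recording.montage
    starts, data = segment(recording, grid)
    rows = []
    for t, seg_data in zip(starts, data):
        powers = {
            "theta": band_power(seg_data, THETA, recording.sample_rate, taper),
            "alpha": band_power(seg_data, ALPHA, recording.sample_rate, taper),
        }
        rows.append(build_dfhm(powers, baseline, m, segment_time=float(t)).vector)
    return starts, np.asarray(rows)


class DFHMExtractor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from recordings to DFHM feature matrices.

    ``fit`` learns the baseline statistics from a recording's first
    ``baseline_window`` seconds; ``transform`` maps a recording to the
    (n_segments, n_features) DFHM matrix. Segment times of the last
    transform are kept in ``times_``.
    """

    def __init__(
        self,
        length: float = 1.0,
        step: float = 0.5,
        baseline_window: float = 60.0,
        taper: str = "rect",
        enforce_preprocessing: bool = False,
    ):
        self.length = length
        self.step = step
        self.baseline_window = baseline_window
        self.taper = taper
        self.enforce_preprocessing = enforce_preprocessing

    def _grid(self) -> SegmentGrid:
        return SegmentGrid(length=self.length, step=self.step)

    def fit(self, recording: EEGRecording, y=None) -> "DFHMExtractor":
        if self.enforce_preprocessing:
            require_preprocessed(recording)
        self.baseline_ = compute_baseline(
            recording, self._grid(), window=self.baseline_window, taper=self.taper
        )
        m = recording.montage
        self.n_features_out_ = len(m.frontal_set) + len(m.parietal_set)
        return self

    def transform(self, recording: EEGRecording) -> np.ndarray:
        if not hasattr(self, "baseline_"):
            raise RuntimeError("DFHMExtractor is not fitted")
        times, X = extract_dfhm_series(
            recording,
            self.baseline_,
            self._grid(),
            taper=self.taper,
            enforce_preprocessing=self.enforce_preprocessing,
        )
        self.times_ = times
        return X


def dfhm_series_to_dataframe(
    times: np.ndarray, X: np.ndarray, montage: Montage
) -> pd.DataFrame:
    """Long CSV-ready layout: (segment_time, electrode, band, z)."""
    names = list(montage.frontal_set) + list(montage.parietal_set)
    bands = ["theta"] * len(montage.frontal_set) + ["alpha"] * len(montage.parietal_set)
    rows = []
    for t, row in zip(times, X):
        for name, band, z in zip(names, bands, row):
            rows.append((float(t), name, band, float(z)))
    return pd.DataFrame(rows, columns=["segment_time", "electrode", "band", "z"])
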