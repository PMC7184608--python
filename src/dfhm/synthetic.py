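"""Synthetic inputs for the workload pipeline.

Three generators cover everything the downstream stages consume:

* :func:`generate_eeg` — 25-channel, 500 Hz EEG whose frontal theta
  (4–8 Hz) and parietal alpha (8–12 Hz) band powers follow a latent
  3-level workload profile. Background activity is band-limited
  1/f-shaped noise; the workload-sensitive rhythms are sinusoids whose
  amplitudes are set per level, so expected band powers are analytically
  checkable (a sinusoid of amplitude a carries power a²/2).
* :func:`inject_artifacts` — seeded ocular (blink) events with a ground
  truth log, for testing ICA-based rejection.
* :func:`generate_labeled_dfhm` — labeled Gaussian clusters in DFHM
  feature space, standing in for a workload-calibration corpus.

The established workload direction is encoded in the defaults: frontal
theta amplitude increases and parietal alpha amplitude decreases with
the latent level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage, standard_montage
from .recording import EEGRecording

__all__ = [
    "LEVELS",
    "WorkloadProfile",
    "GeneratorConfig",
    "generate_eeg",
    "inject_artifacts",
    "generate_labeled_dfhm",
    "profile_for_index",
    "BLINK_AMPLITUDE_UV",
]

LEVELS = ("low", "moderate", "high")
LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}

#: peak blink amplitude in µV; dominates the ~5 µV background on frontal sites
BLINK_AMPLITUDE_UV = 120.0


@dataclass(frozen=True)
class WorkloadProfile:
    """Piecewise-constant latent workload: ``breaks[i] .. breaks[i+1]`` is
    held at ``levels[i]``. ``breaks`` starts at 0 and is strictly increasing."""

    breaks: tuple[float, ...]
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.levels) + 1:
            raise ValueError("need len(breaks) == len(levels) + 1")
        if not self.levels:
            raise ValueError("profile needs at least one interval")
        b = np.asarray(self.breaks, dtype=float)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("breaks must start at 0 and be strictly increasing")
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown workload levels: {sorted(unknown)}")

    @property
    def duration(self) -> float:
        return float(self.breaks[-1])

    @classmethod
    def constant(cls, level: str, duration: float) -> "WorkloadProfile":
        return cls(breaks=(0.0, float(duration)), levels=(level,))

    def level_at(self, t: np.ndarray) -> np.ndarray:
        """Integer level index (0/1/2) for each time in ``t``."""
        idx = np.searchsorted(np.asarray(self.breaks), t, side="right") - 1
        idx = np.clip(idx, 0, len(self.levels) - 1)
        codes = np.asarray([LEVEL_INDEX[lv] for lv in self.levels])
        return codes[idx]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the EEG generator; the seed fully determines the output."""

    montage: Montage = field(default_factory=standard_montage)
    sample_rate: float = 500.0
    theta_freq: float = 6.0
    alpha_freq: float = 10.0
    #: sinusoid amplitude (µV) on frontal channels per level — increasing
    theta_gain_per_level: tuple[float, float, float] = (2.0, 4.0, 6.0)
    #: sinusoid amplitude (µV) on parietal channels per level — decreasing
    alpha_gain_per_level: tuple[float, float, float] = (6.0, 4.0, 2.0)
    noise_sd: float = 5.0  # µV, background 1/f noise
    noise_band: tuple[float, float] = (0.5, 40.0)
    artifact_rate: float = 0.0  # blink events per minute
    seed: int = 0

    def __post_init__(self) -> None:
        top = max(self.theta_freq, self.alpha_freq, self.noise_band[1])
        if self.sample_rate <= 2 * top:
            raise ValueError(
                f"sample rate {self.sample_rate} Hz below Nyquist for "
                f"synthesized content up to {top} Hz"
            )
        if np.any(np.diff(self.theta_gain_per_level) <= 0):
            raise ValueError("theta gains must strictly increase with level")
        if np.any(np.diff(self.alpha_gain_per_level) >= 0):
            raise ValueError("alpha gains must strictly decrease with level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      band: tuple[float, float], sd: float) -> np.ndarray:
    """Band-limited noise with 1/f amplitude shaping, scaled to std ``sd``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    shape[inside] = 1.0 / np.sqrt(freqs[inside])
    spec = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def generate_eeg(profile: WorkloadProfile, config: GeneratorConfig) -> EEGRecording:
    """Synthesize a multichannel recording following a workload profile.

    Frontal channels carry a theta sinusoid whose amplitude tracks the
    profile through ``theta_gain_per_level``; parietal channels carry an
    alpha sinusoid with ``alpha_gain_per_level``; every channel gets
    independent 1/f background noise. Each channel's oscillation has a
    seeded random phase. Identical (profile, config) pairs give
    bitwise-identical recordings.
    """
    if profile.duration <= 0:
        raise ValueError("zero-duration profile")
    fs = config.sample_rate
    n = int(round(profile.duration * fs))
    if n < 1:
        raise ValueError("profile too short for one sample")
    m = config.montage
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs
    lvl = profile.level_at(t)
    theta_amp = np.asarray(config.theta_gain_per_level)[lvl]
    alpha_amp = np.asarray(config.alpha_gain_per_level)[lvl]

    frontal = set(m.frontal_set)
    parietal = set(m.parietal_set)
    samples = np.zeros((m.n_channels, n))
    for ci, name in enumerate(m.channel_names):
        phase = rng.uniform(0, 2 * np.pi)
        noise = (
            _one_over_f_noise(rng, n, fs, config.noise_band, config.noise_sd)
            if config.noise_sd > 0
            else 0.0
        )
        x = np.zeros(n) + noise
        if name in frontal:
            x = x + theta_amp * np.sin(2 * np.pi * config.theta_freq * t + phase)
        elif name in parietal:
            x = x + alpha_amp * np.sin(2 * np.pi * config.alpha_freq * t + phase)
        if name == m.reference:
            x = np.zeros(n)  # acquisition reference carries no signal
        samples[ci] = x

    rec = EEGRecording(
        samples=samples,
        sample_rate=fs,
        montage=m,
        provenance=[f"synthetic(seed={config.seed})"],
    )
    if config.artifact_rate > 0:
        rec, _ = inject_artifacts(rec, config.artifact_rate, seed=config.seed + 1)
    return rec


def _blink_template(n: int) -> np.ndarray:
    """Biphasic low-frequency pulse (one full sine cycle over the event)."""
    return np.sin(2 * np.pi * np.arange(n) / n)


def _frontal_weights(montage: Montage) -> np.ndarray:
    """Per-channel blink projection: exponential falloff from the forehead."""
    anchor = np.array([0.0, 1.0])
    w = np.empty(montage.n_channels)
    for i, name in enumerate(montage.channel_names):
        pos = np.asarray(montage.positions[name])
        w[i] = np.exp(-np.linalg.norm(pos - anchor) / 0.45)
    w[montage.index(montage.reference)] = 0.0
    return w


def inject_artifacts(
    recording: EEGRecording, rate: float, seed: int
) -> tuple[EEGRecording, list[dict]]:
    """Add seeded blink events at ``rate`` events/min; returns (recording, log).

    Each log entry records onset, duration and peak amplitude. Events are
    Poisson-counted, uniformly placed, and projected onto the scalp with
    frontal dominance. ``rate = 0`` returns an identical copy and an empty log.
    """
    if rate < 0:
        raise ValueError("artifact rate must be >= 0")
    if rate == 0:
        return recording.copy(), []
    rng = np.random.default_rng(seed)
    fs = recording.sample_rate
    dur = recording.duration
    n_events = int(rng.poisson(rate * dur / 60.0))
    weights = _frontal_weights(recording.montage)
    samples = recording.samples.copy()
    log: list[dict] = []
    for _ in range(n_events):
        ev_dur = float(rng.uniform(0.1, 0.3))
        onset = float(rng.uniform(0, max(dur - ev_dur, 0)))
        i0 = int(round(onset * fs))
        i1 = min(i0 + int(round(ev_dur * fs)), recording.n_times)
        if i1 <= i0:
            continue
        pulse = BLINK_AMPLITUDE_UV * _blink_template(i1 - i0)
        samples[:, i0:i1] += weights[:, None] * pulse[None, :]
        log.append({"onset": onset, "duration": ev_dur,
                    "amplitude": BLINK_AMPLITUDE_UV, "template": "blink"})
    log.sort(key=lambda e: e["onset"])
    out = recording.with_samples(samples, f"inject_artifacts(rate={rate},seed={seed})")
    return out, log


def write_artifact_log(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=1)


def read_artifact_log(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)


def generate_labeled_dfhm(
    n_per_class: int,
    separation: float,
    dim: int = 14,
    seed: int = 0,
    montage: Montage | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled DFHM-space clusters for classifier calibration.

    Class k (0 = low, 1 = moderate, 2 = high) has mean (k − 1) · separation ·
    u where u is the unit vector that is positive on the frontal-theta half
    of the feature vector and negative on the parietal-alpha half — higher
    workload means more frontal theta and less parietal alpha. Noise is unit
    isotropic Gaussian. Returns (X, y) with balanced classes.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if montage is not None:
        expected = len(montage.frontal_set) + len(montage.parietal_set)
        if dim != expected:
            raise ValueError(f"dim {dim} inconsistent with montage (expects {expected})")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    half = dim // 2
    u = np.concatenate([np.ones(dim - half), -np.ones(half)])
    u /= np.linalg.norm(u)
    X = np.empty((3 * n_per_class, dim))
    y = np.repeat(np.arange(3), n_per_class)
    for k in range(3):
        center = (k - 1) * separation * u
        X[k * n_per_class:(k + 1) * n_per_class] = center + rng.standard_normal(
            (n_per_class, dim)
        )
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def profile_for_index(
    target_index: float, duration: float, step: float = 0.5, seed: int = 0
) -> WorkloadProfile:
    """A stochastic profile whose expected 0–100 index is ``target_index``.

    Labels are drawn i.i.d. per ``step`` with a fixed moderate share of 0.3
    and P(high) = clip((I − 15)/100, 0, 0.7), which makes the expected index
    50·0.3 + 100·P(high) = I on the interior of the scale.
    """
    if not 0 <= target_index <= 100:
        raise ValueError("target index must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(duration / step)))
    p_mod = 0.3
    p_high = float(np.clip((target_index - 15.0) / 100.0, 0.0, 1.0 - p_mod))
    p_low = 1.0 - p_mod - p_high
    draws = rng.choice(3, size=n, p=[p_low, p_mod, p_high])
    breaks = tuple(np.round(np.arange(n + 1) * step, 10))
    breaks = breaks[:-1] + (float(duration),)
    return WorkloadProfile(breaks=breaks, levels=tuple(LEVELS[d] for d in draws))
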