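"""In-memory EEG container and its plain-text interchange formats."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage, standard_montage

__all__ = ["EEGRecording", "read_csv", "read_edf"]


@dataclass
class EEGRecording:
    """Multichannel EEG: ``samples`` is a (n_channels, n_times) array in µV.

    ``provenance`` is an append-only list of the operations applied so far;
    the feature stage uses it to verify the conditioning order.
    """

    samples: np.ndarray
    sample_rate: float
    montage: Montage
    reference_state: str = "original"  # {"original", "average"}
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels × time)")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.samples.shape[0]} rows for a "
                f"{self.montage.n_channels}-channel montage"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_times / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sample_rate

    def copy(self) -> "EEGRecording":
        return replace(self, samples=self.samples.copy(), provenance=list(self.provenance))

    def with_samples(self, samples: np.ndarray, step: str, **changes) -> "EEGRecording":
        """Copy with new samples and ``step`` appended to provenance."""
        return replace(
            self,
            samples=np.asarray(samples, dtype=float),
            provenance=[*self.provenance, step],
            **changes,
        )

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.montage.index(name)]

    # -- text interchange -------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (time, channel) with amplitude in µV."""
        t = self.times
        return pd.DataFrame(
            {
                "time": np.repeat(t, self.n_channels),
                "channel": np.tile(np.asarray(self.montage.channel_names), self.n_times),
                "uV": self.samples.T.reshape(-1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_csv(path, sample_rate: float | None = None, montage: Montage | None = None) -> EEGRecording:
    """Read the long-format CSV written by :meth:`EEGRecording.to_csv`."""
    df = pd.read_csv(path)
    wide = df.pivot(index="time", columns="channel", values="uV").sort_index()
    if sample_rate is None:
        dt = np.diff(wide.index.to_numpy())
        sample_rate = 1.0 / float(np.median(dt))
    montage = montage or standard_montage()
    missing = set(montage.channel_names) - set(wide.columns)
    if missing:
        raise ValueError(f"CSV lacks montage channels: {sorted(missing)}")
    samples = wide[list(montage.channel_names)].to_numpy().T
    return EEGRecording(samples, float(sample_rate), montage)


def read_edf(path, montage: Montage | None = None) -> EEGRecording:
    """Read an EDF file (via mne) into an :class:`EEGRecording`.

    Channels are matched to the montage by name; units are converted to µV.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    montage = montage or standard_montage()
    missing = set(montage.channel_names) - set(raw.ch_names)
    if missing:
        raise ValueError(f"EDF lacks montage channels: {sorted(missing)}")
    data = raw.get_data(picks=list(montage.channel_names)) * 1e6
    return EEGRecording(data, float(raw.info["sfreq"]), montage)
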