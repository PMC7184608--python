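"""25-channel 10-20 montage with a Hjorth neighbourhood structure.

The montage carries 2-D head-schematic coordinates (x: left → right,
y: back → front, unit head radius), a symmetric neighbour map capped at
8 neighbours per channel, and the frontal/parietal electrode subsets
that the Dual Frequency Head Map is built from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "MontageError", "standard_montage", "STANDARD_CHANNELS"]


class MontageError(ValueError):
    """Raised when a montage violates its structural invariants."""


#: 25 electrode positions of the extended 10-20 layout used for acquisition.
#: Coordinates are schematic (unit circle = head outline).
STANDARD_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.58), "Fz": (0.0, 0.55),
    "F4": (0.40, 0.58), "F8": (0.81, 0.59),
    "FC3": (-0.45, 0.28), "FCz": (0.0, 0.28), "FC4": (0.45, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP3": (-0.45, -0.28), "CPz": (0.0, -0.28), "CP4": (0.45, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.58), "Pz": (0.0, -0.55),
    "P4": (0.40, -0.58), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

STANDARD_CHANNELS: tuple[str, ...] = tuple(STANDARD_POSITIONS)

DEFAULT_FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
DEFAULT_PARIETAL = ("P7", "P3", "Pz", "P4", "P8", "O1", "O2")


def _build_neighbours(
    names: tuple[str, ...],
    positions: dict[str, tuple[float, float]],
    max_neighbours: int = 8,
) -> dict[str, tuple[str, ...]]:
    """Nearest-neighbour map, capped at ``max_neighbours`` and symmetrized.

    Border electrodes keep fewer than 8 neighbours: a channel only links to
    the capped nearest set, and the relation is symmetrized by intersection
    so both endpoints must agree, which prevents long links across the scalp.
    """
    coords = np.asarray([positions[n] for n in names], dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nearest = [set(np.argsort(d[i])[:max_neighbours].tolist()) for i in range(len(names))]
    out: dict[str, tuple[str, ...]] = {}
    for i, name in enumerate(names):
        mutual = sorted(j for j in nearest[i] if i in nearest[j])
        out[name] = tuple(names[j] for j in mutual)
    return out


@dataclass(frozen=True)
class Montage:
    """Electrode layout plus the subsets the workload features are read from."""

    channel_names: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    neighbours: dict[str, tuple[str, ...]]
    frontal_set: tuple[str, ...] = DEFAULT_FRONTAL
    parietal_set: tuple[str, ...] = DEFAULT_PARIETAL
    reference: str = "Cz"

    def __post_init__(self) -> None:
        names = set(self.channel_names)
        if len(names) != len(self.channel_names):
            raise MontageError("duplicate channel names")
        if self.reference not in names:
            raise MontageError(f"reference {self.reference!r} not in montage")
        if not self.frontal_set or not self.parietal_set:
            raise MontageError("frontal and parietal sets must be non-empty")
        if set(self.frontal_set) & set(self.parietal_set):
            raise MontageError("frontal and parietal sets must be disjoint")
        for sub in (self.frontal_set, self.parietal_set):
            missing = set(sub) - names
            if missing:
                raise MontageError(f"set members not in montage: {sorted(missing)}")
        for ch, nbrs in self.neighbours.items():
            if len(nbrs) < 1:
                raise MontageError(f"channel {ch!r} has no neighbours")
            for nb in nbrs:
                if ch not in self.neighbours.get(nb, ()):
                    raise MontageError(f"neighbour relation not symmetric: {ch}–{nb}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def indices(self, names) -> np.ndarray:
        return np.asarray([self.index(n) for n in names], dtype=int)

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "channel_names": list(self.channel_names),
            "positions": {k: list(v) for k, v in self.positions.items()},
            "neighbours": {k: list(v) for k, v in self.neighbours.items()},
            "frontal_set": list(self.frontal_set),
            "parietal_set": list(self.parietal_set),
            "reference": self.reference,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            channel_names=tuple(payload["channel_names"]),
            positions={k: tuple(v) for k, v in payload["positions"].items()},
            neighbours={k: tuple(v) for k, v in payload["neighbours"].items()},
            frontal_set=tuple(payload["frontal_set"]),
            parietal_set=tuple(payload["parietal_set"]),
            reference=payload["reference"],
        )


def standard_montage(
    frontal_set=DEFAULT_FRONTAL,
    parietal_set=DEFAULT_PARIETAL,
    max_neighbours: int = 8,
) -> Montage:
    """The default 25-channel montage (Cz acquisition reference).

    Cz is excluded from both feature sets: as the acquisition reference it
    carries no signal of its own until re-referencing.
    """
    return Montage(
        channel_names=STANDARD_CHANNELS,
        positions=dict(STANDARD_POSITIONS),
        neighbours=_build_neighbours(STANDARD_CHANNELS, STANDARD_POSITIONS, max_neighbours),
        frontal_set=tuple(frontal_set),
        parietal_set=tuple(parietal_set),
    )
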