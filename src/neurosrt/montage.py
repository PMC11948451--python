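"""Electrode montage positions on the unit sphere (10-20 system)."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["MontagePositions", "biosemi64_montage"]


@dataclass
class MontagePositions:
    """Per-channel unit vectors on a sphere with their labels."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms == 0):
            raise ValueError("montage contains a zero position vector")
        self.positions = self.positions / norms[:, None]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels) -> "MontagePositions":
        idx = [self.labels.index(l) for l in labels]
        return MontagePositions([self.labels[i] for i in idx], self.positions[idx])

    @classmethod
    def from_table(cls, path) -> "MontagePositions":
        """Read an electrode-position table (columns: label, x, y, z)."""
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["label"].tolist(), df[["x", "y", "z"]].to_numpy(float))


@lru_cache(maxsize=1)
def biosemi64_montage() -> MontagePositions:
    """The 64-channel BioSemi cap layout, normalized to the unit sphere."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    ch_pos = montage.get_positions()["ch_pos"]
    labels = list(ch_pos)
    pos = np.array([ch_pos[l] for l in labels])
    return MontagePositions(labels, pos)
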