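"""64-channel BioSemi-style montage on the extended 10-20 layout.

Positions come from MNE's standard ``biosemi64`` template and are
renormalised to the unit sphere so great-circle distances are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Montage", "ROI_CHANNELS", "default_montage"]

#: A-priori regions of interest: medial occipital, left and right occipito-parietal.
ROI_CHANNELS = {
    "MO": ("O1", "Iz", "Oz", "O2"),
    "LOP": ("P5", "P7", "P9", "PO7"),
    "ROP": ("P6", "P8", "P10", "PO8"),
}


@dataclass
class Montage:
    """Channel labels with unit-sphere 3-D positions."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), unit norm rows

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        norms = np.linalg.norm(self.positions, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-norm electrode position")
        self.positions = self.positions / norms
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def great_circle_distances(self, label: str) -> np.ndarray:
        """Angular distance (radians) from one electrode to every electrode."""
        ref = self.positions[self.index(label)]
        cosine = np.clip(self.positions @ ref, -1.0, 1.0)
        return np.arccos(cosine)

    def distances_from_point(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        p = p / np.linalg.norm(p)
        return np.arccos(np.clip(self.positions @ p, -1.0, 1.0))


def default_montage() -> Montage:
    """The 64-channel biosemi64 template montage (all 12 ROI electrodes included)."""
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    pos = std.get_positions()["ch_pos"]
    labels = list(std.ch_names)
    xyz = np.array([pos[ch] for ch in labels])
    m = Montage(labels=labels, positions=xyz)
    missing = [ch for roi in ROI_CHANNELS.values() for ch in roi if ch not in m._index]
    if missing:
        raise RuntimeError(f"montage template lacks ROI electrodes: {missing}")
    return m
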