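"""Sensor layout: 64-channel 10-20 positions in normalized 2-D coordinates.

The canonical layout is the BioSemi 64-electrode montage. 3-D electrode
positions are flattened with an azimuthal-equidistant projection (angle from
the vertex becomes planar radius) and scaled so the outermost electrode sits
at radius 1; neighbor radii such as 0.5 are expressed in these normalized
units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorLayout", "biosemi64_layout"]


@dataclass(frozen=True)
class SensorLayout:
    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), normalized

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances in normalized units."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def neighbors(self, name: str, radius: float) -> list[str]:
        """Channels (excluding ``name``) within ``radius`` normalized units."""
        i = self.index(name)
        d = self.distances()[i]
        return [
            c
            for j, c in enumerate(self.channel_names)
            if j != i and d[j] <= radius
        ]


def _azimuthal_equidistant(xyz: np.ndarray) -> np.ndarray:
    # Angle from the vertex (+z) maps to planar radius; azimuth is preserved.
    x, y, z = xyz.T
    r3 = np.linalg.norm(xyz, axis=1)
    polar = np.arccos(np.clip(z / r3, -1.0, 1.0))
    azim = np.arctan2(y, x)
    return np.column_stack([polar * np.cos(azim), polar * np.sin(azim)])


def biosemi64_layout() -> SensorLayout:
    """The standard 64-channel BioSemi montage as a normalized 2-D layout."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    ch_pos = montage.get_positions()["ch_pos"]
    names = tuple(ch_pos.keys())
    xyz = np.array([ch_pos[n] for n in names], dtype=float)
    pos2d = _azimuthal_equidistant(xyz)
    pos2d /= np.abs(np.linalg.norm(pos2d, axis=1)).max()
    return SensorLayout(names, pos2d)
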