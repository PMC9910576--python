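"""28-channel 10-20 montage: labels, positions, spatial clusters, adjacency.

The canonical recording setup is 28 active scalp electrodes in a 10-20
layout. For regional aggregation the electrodes are grouped into eight
spatial clusters (frontopolar, frontocentral, frontal, temporal, central,
centroparietal, parietal, occipital) that partition the montage exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: The 28 scalp channels, ordered front to back, left to right.
CHANNELS_28: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Eight spatial clusters partitioning the 28 channels (2+5+4+2+3+4+5+3).
CLUSTERS_8: dict[str, tuple[str, ...]] = {
    "frontopolar": ("Fp1", "Fp2"),
    "frontocentral": ("FC1", "FC2", "Fz", "FC5", "FC6"),
    "frontal": ("F3", "F4", "F7", "F8"),
    "temporal": ("T7", "T8"),
    "central": ("C3", "Cz", "C4"),
    "centroparietal": ("CP1", "CP2", "CP5", "CP6"),
    "parietal": ("P3", "P4", "P7", "P8", "Pz"),
    "occipital": ("O1", "O2", "Oz"),
}


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode labels with unit-sphere head positions.

    Parameters
    ----------
    labels
        Unique channel names.
    positions
        ``(n_channels, 3)`` coordinates, normalized onto the unit sphere.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions must be ({len(self.labels)}, 3), got {pos.shape}"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length electrode position")
        object.__setattr__(self, "positions", pos / norms[:, None])

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def positions_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection of the electrode sphere to 2-D."""
        x, y, z = self.positions.T
        theta = np.arccos(np.clip(z, -1.0, 1.0))
        phi = np.arctan2(y, x)
        return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])

    def cluster_indices(
        self, clusters: dict[str, tuple[str, ...]] | None = None
    ) -> dict[str, np.ndarray]:
        """Map cluster name -> channel indices; clusters must partition."""
        clusters = CLUSTERS_8 if clusters is None else clusters
        seen: list[str] = []
        out = {}
        for name, chans in clusters.items():
            missing = [c for c in chans if c not in self.labels]
            if missing:
                raise ValueError(f"cluster {name!r} references unknown channels {missing}")
            seen.extend(chans)
            out[name] = np.array([self.index(c) for c in chans], dtype=int)
        if sorted(seen) != sorted(self.labels):
            raise ValueError("clusters must partition the montage exactly")
        return out


def default_layout() -> ChannelLayout:
    """The 28-channel 10-20 layout with standard template head positions."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    ch_pos = montage.get_positions()["ch_pos"]
    pos = np.array([ch_pos[label] for label in CHANNELS_28])
    return ChannelLayout(labels=CHANNELS_28, positions=pos)


def channel_adjacency(layout: ChannelLayout) -> np.ndarray:
    """Boolean channel-neighbor matrix from a Delaunay triangulation.

    Two electrodes are neighbors iff they share a Delaunay edge in the 2-D
    projected montage.  Symmetric, zero diagonal.
    """
    from scipy.spatial import Delaunay

    pts = layout.positions_2d
    tri = Delaunay(pts)
    n = len(layout)
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    adj[i, j] = True
    return adj
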