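"""Electrode layout: labels, 2-D scalp positions, and spatial adjacency.

The default layout is the 32-channel BioSemi arrangement of the
international 10-10 system plus two infra-orbital EOG electrodes.  Scalp
positions come from the standard montage shipped with MNE, projected to
2-D by azimuthal-equidistant mapping; the neighbour relation used for the
Hjorth surface Laplacian and for spatial clustering is the Delaunay
triangulation of those positions with implausibly long edges pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

# BioSemi 32-channel ordering (matches the vendor cap and MNE's montage).
BIOSEMI32_LABELS: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)
EOG_LABELS: tuple[str, ...] = ("EOG1", "EOG2")

# Edges longer than this multiple of the median Delaunay edge are pruned
# (removes the long chords the convex hull introduces across the scalp rim).
_EDGE_PRUNE_FACTOR = 1.6


def canonical_label(name: str) -> str:
    """Normalize a vendor channel name to its canonical 10-10 form.

    Strips whitespace and reference suffixes, then case-folds against the
    known labels, so ``"FP1"``, ``" fp1 "`` and ``"Fp1"`` all resolve to
    ``"Fp1"``.  Unknown names are returned stripped but otherwise unchanged.
    """
    name = name.strip()
    for cand in BIOSEMI32_LABELS + EOG_LABELS:
        if name.lower() == cand.lower():
            return cand
    return name


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel set with scalp geometry and neighbour structure.

    Parameters
    ----------
    labels : tuple of str
        All channel names, scalp channels first.
    positions : ndarray, shape (n_scalp, 2)
        2-D scalp coordinates of the scalp channels (head-centred,
        arbitrary units).
    adjacency : ndarray, shape (n_scalp, n_scalp) of bool
        Symmetric, irreflexive spatial neighbour relation over scalp
        channels.
    channel_kind : tuple of str
        ``"scalp"`` or ``"eog"`` per label.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    adjacency: np.ndarray
    channel_kind: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        kinds = self.channel_kind or tuple(
            "eog" if lab in EOG_LABELS else "scalp" for lab in self.labels
        )
        object.__setattr__(self, "channel_kind", kinds)
        n_scalp = len(self.scalp_labels)
        if self.positions.shape != (n_scalp, 2):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n_scalp}, 2)"
            )
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (n_scalp, n_scalp):
            raise ValueError("adjacency must be square over scalp channels")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        if n_scalp > 1 and not adj.any(axis=1).all():
            raise ValueError("every scalp channel needs at least one neighbour")
        object.__setattr__(self, "adjacency", adj)

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        return tuple(
            lab for lab, k in zip(self.labels, self.channel_kind) if k == "scalp"
        ) if self.channel_kind else tuple(
            lab for lab in self.labels if lab not in EOG_LABELS
        )

    @property
    def eog_labels(self) -> tuple[str, ...]:
        return tuple(
            lab for lab, k in zip(self.labels, self.channel_kind) if k == "eog"
        )

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_labels)

    def __len__(self) -> int:
        return len(self.labels)

    def scalp_indices(self) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.channel_kind) if k == "scalp"], dtype=int
        )

    def eog_indices(self) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.channel_kind) if k == "eog"], dtype=int
        )

    def neighbours(self, label: str) -> tuple[str, ...]:
        scalp = self.scalp_labels
        i = scalp.index(canonical_label(label))
        return tuple(scalp[j] for j in np.flatnonzero(self.adjacency[i]))


def _azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Project 3-D electrode positions onto the plane.

    Azimuthal-equidistant projection about the vertex: the polar angle from
    +z becomes the radius, preserving angular distance from Cz.
    """
    x, y, z = pos3d.T
    r = np.linalg.norm(pos3d, axis=1)
    theta = np.arccos(np.clip(z / np.where(r > 0, r, 1.0), -1.0, 1.0))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def delaunay_adjacency(pos2d: np.ndarray, prune_factor: float = _EDGE_PRUNE_FACTOR) -> np.ndarray:
    """Neighbour relation from the Delaunay triangulation of 2-D positions.

    Edges longer than ``prune_factor`` times the median edge length are
    dropped unless removal would isolate a node.
    """
    n = len(pos2d)
    adj = np.zeros((n, n), dtype=bool)
    tri = Delaunay(pos2d)
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            adj[i, j] = adj[j, i] = True
    lengths = {
        (i, j): float(np.linalg.norm(pos2d[i] - pos2d[j]))
        for i in range(n)
        for j in range(i + 1, n)
        if adj[i, j]
    }
    cutoff = prune_factor * float(np.median(list(lengths.values())))
    # prune longest-first so degree checks see the current graph
    for (i, j), d in sorted(lengths.items(), key=lambda kv: -kv[1]):
        if d > cutoff and adj[i].sum() > 1 and adj[j].sum() > 1:
            adj[i, j] = adj[j, i] = False
    return adj


def default_layout() -> ChannelLayout:
    """The 32-channel BioSemi 10-10 layout with two EOG channels."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi32")
    ch_pos = montage.get_positions()["ch_pos"]
    pos3d = np.array([ch_pos[lab] for lab in BIOSEMI32_LABELS])
    pos2d = _azimuthal_projection(pos3d)
    adjacency = delaunay_adjacency(pos2d)
    return ChannelLayout(
        labels=BIOSEMI32_LABELS + EOG_LABELS,
        positions=pos2d,
        adjacency=adjacency,
    )
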