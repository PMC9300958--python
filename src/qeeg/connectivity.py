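"""Alpha-envelope mutual-information connectivity and global efficiency.

The chain: Hjorth surface-Laplacian re-reference, zero-phase alpha-band
filtering, Hilbert amplitude envelope, binned mutual information between
every channel pair (equipopulated bins, Panzeri-Treves bias correction),
participant-specific binarization at 80% of the air-baseline matrix range,
and unweighted graph global efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import signal

from qeeg.io import StudyConfig, logger
from qeeg.layout import ChannelLayout
from qeeg.preprocess import EpochSet

_LN2 = np.log(2.0)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-pair MI in bits; the diagonal is not meaningful."""

    mi: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mi = np.asarray(self.mi, dtype=float)
        n = self.mi.shape[0]
        if self.mi.shape != (n, n):
            raise ValueError("MI matrix must be square")
        if not np.allclose(self.mi, self.mi.T, atol=1e-12):
            raise ValueError("MI matrix must be symmetric")

    def offdiag(self) -> np.ndarray:
        n = self.mi.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.mi[iu]

    def nodal_strength(self) -> np.ndarray:
        """Mean off-diagonal MI per channel (used as the per-channel map
        entering the spatiospectral cluster test)."""
        n = self.mi.shape[0]
        m = self.mi.copy()
        np.fill_diagonal(m, 0.0)
        return m.sum(axis=1) / (n - 1)


@dataclass
class BinaryGraph:
    """Thresholded adjacency with the participant-specific threshold used."""

    adjacency: np.ndarray
    threshold: float
    threshold_source: str = ""

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = adj.astype(bool)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def hjorth_reference(ep: EpochSet, layout: ChannelLayout) -> EpochSet:
    """Local-Laplacian re-reference: each channel minus its neighbour mean.

    Neighbourhoods come from the layout's spatial adjacency; edge
    electrodes use whatever neighbours they have.
    """
    labels = ep.channel_labels
    scalp = layout.scalp_labels
    if labels != scalp:
        # allow permuted channel order as long as the set matches
        if set(labels) != set(scalp):
            raise ValueError("epoch channels do not match the layout scalp set")
    order = [scalp.index(lab) for lab in labels]
    adj = layout.adjacency[np.ix_(order, order)]
    deg = adj.sum(axis=1)
    if (deg == 0).any():
        bad = [labels[i] for i in np.flatnonzero(deg == 0)]
        raise ValueError(f"channels without neighbours: {bad}")
    w = adj / deg[:, None]
    referenced = ep.epochs - np.einsum("ij,ejs->eis", w, ep.epochs)
    return EpochSet(
        epochs=referenced,
        fs=ep.fs,
        epoch_length=ep.epoch_length,
        channel_labels=labels,
        provenance={**ep.provenance, "reference": "hjorth"},
    )


def alpha_envelope(
    ep: EpochSet, band: tuple[float, float] = (8.0, 14.0)
) -> np.ndarray:
    """Per-epoch amplitude envelope of the band-passed signal.

    Zero-phase 4th-order Butterworth band-pass followed by the magnitude
    of the analytic (Hilbert) signal.  Returns
    ``[n_epochs, n_channels, n_samples]`` of non-negative envelopes.
    """
    lo, hi = band
    if not (0.0 < lo < hi < ep.fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=ep.fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if ep.n_samples <= padlen:
        raise ValueError("epoch shorter than the filter transient allowance")
    filtered = signal.sosfiltfilt(sos, ep.epochs, axis=-1)
    return np.abs(signal.hilbert(filtered, axis=-1))


def _equipopulated_labels(x: np.ndarray, bins: int) -> np.ndarray | None:
    """Rank-based equal-mass discretization; None for a constant series."""
    if np.ptp(x) == 0:
        return None
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * bins) // len(x)


def _mi_from_joint(joint: np.ndarray, n: int, bias_correction: bool) -> float:
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = px[:, None] * py[None, :]
    mi = float((p[nz] * np.log2(p[nz] / outer[nz])).sum())
    if bias_correction:
        bias = (nz.sum() - (px > 0).sum() - (py > 0).sum() + 1) / (2 * n * _LN2)
        mi -= bias
    return max(mi, 0.0) if bias_correction else mi


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    bins: int = 4,
    bias_correction: bool = True,
) -> float:
    """Binned mutual information in bits between two series.

    Both series are discretized into ``bins`` equipopulated bins; the
    plug-in estimate is corrected with the Panzeri-Treves first-order bias
    term and clipped at zero.  Symmetric in its arguments.  A constant
    series (equipopulated bins undefined) yields 0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal lengths")
    if len(x) < 64:
        raise ValueError("series too short for a stable MI estimate (need >= 64)")
    lx = _equipopulated_labels(x, bins)
    ly = _equipopulated_labels(y, bins)
    if lx is None or ly is None:
        warnings.warn("constant series: MI undefined, returning 0", stacklevel=2)
        return 0.0
    joint = np.bincount(lx * bins + ly, minlength=bins * bins).reshape(bins, bins)
    return _mi_from_joint(joint, len(x), bias_correction)


def _pairwise_mi(labels: np.ndarray, bins: int, bias_correction: bool) -> np.ndarray:
    """All-pairs binned MI from per-channel discretized labels.

    ``labels`` is ``[n_channels, n]`` of ints in ``0..bins-1`` (rows that
    were constant hold -1 and produce zero MI).
    """
    n_ch, n = labels.shape
    mi = np.zeros((n_ch, n_ch))
    for i in range(n_ch - 1):
        if labels[i, 0] < 0:
            continue
        rest = labels[i + 1 :]
        valid = rest[:, 0] >= 0
        if not valid.any():
            continue
        idx = labels[i] * bins + rest[valid]
        m = idx.shape[0]
        flat = (np.arange(m)[:, None] * (bins * bins) + idx).ravel()
        counts = np.bincount(flat, minlength=m * bins * bins).reshape(m, bins, bins)
        p = counts / n
        px = p.sum(axis=2)
        py = p.sum(axis=1)
        outer = px[:, :, None] * py[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / np.where(outer > 0, outer, 1.0)), 0.0)
        vals = terms.sum(axis=(1, 2))
        if bias_correction:
            r_xy = (counts > 0).sum(axis=(1, 2))
            r_x = (px > 0).sum(axis=1)
            r_y = (py > 0).sum(axis=1)
            vals = vals - (r_xy - r_x - r_y + 1) / (2 * n * _LN2)
            vals = np.maximum(vals, 0.0)
        cols = np.flatnonzero(valid) + i + 1
        mi[i, cols] = vals
        mi[cols, i] = vals
    return mi


def connectivity_matrix(
    ep: EpochSet,
    layout: ChannelLayout,
    cfg: StudyConfig | None = None,
) -> ConnectivityMatrix:
    """Alpha-envelope MI between every channel pair.

    Hjorth re-reference, alpha-band envelope, per-epoch edge trimming
    (zero-phase filter transients), then binned MI on the envelopes
    concatenated across epochs (or per-epoch MI averaged when
    ``cfg.mi_per_epoch``).
    """
    cfg = cfg or StudyConfig()
    band = tuple(cfg.bands["alpha"])
    env = alpha_envelope(hjorth_reference(ep, layout), band)
    trim = int(round(cfg.envelope_trim * ep.fs))
    if 2 * trim >= ep.n_samples:
        raise ValueError("envelope trim leaves no samples")
    env = env[:, :, trim : ep.n_samples - trim]

    def discretize(block: np.ndarray) -> np.ndarray:
        out = np.empty(block.shape, dtype=np.int64)
        for c in range(block.shape[0]):
            lab = _equipopulated_labels(block[c], cfg.mi_bins)
            out[c] = -1 if lab is None else lab
        return out

    if cfg.mi_per_epoch:
        mats = []
        for e in range(env.shape[0]):
            labels = discretize(env[e])
            mats.append(_pairwise_mi(labels, cfg.mi_bins, cfg.mi_bias_correction))
        mi = np.mean(mats, axis=0)
    else:
        concat = env.transpose(1, 0, 2).reshape(env.shape[1], -1)
        labels = discretize(concat)
        mi = _pairwise_mi(labels, cfg.mi_bins, cfg.mi_bias_correction)
    logger.debug("connectivity: median off-diag MI %.4f bits", float(np.median(mi)))
    return ConnectivityMatrix(mi=mi, channel_labels=ep.channel_labels)


def binarize(m: ConnectivityMatrix, baseline: ConnectivityMatrix,
             fraction: float = 0.8, source: str = "air_baseline") -> BinaryGraph:
    """Threshold a matrix at ``min + fraction * range`` of the baseline.

    The threshold is computed once from the participant's air-baseline
    off-diagonal entries and applied to every exposure of that
    participant; an edge is present iff ``mi >= threshold``.
    """
    base = baseline.offdiag()
    lo, hi = float(base.min()), float(base.max())
    if hi <= lo:
        raise ValueError("degenerate baseline matrix (max == min)")
    t = lo + fraction * (hi - lo)
    adj = m.mi >= t
    np.fill_diagonal(adj, False)
    adj &= adj.T  # symmetric by construction; keep it explicit
    return BinaryGraph(adjacency=adj, threshold=t, threshold_source=source)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over all node pairs.

    1 for a complete graph, 0 for an edgeless one; disconnected pairs
    contribute zero.
    """
    if g.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    graph = nx.from_numpy_array(g.adjacency.astype(int))
    return float(nx.global_efficiency(graph))
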