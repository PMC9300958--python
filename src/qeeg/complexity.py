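"""Recurrence-entropy temporal complexity and the DMN summary.

Per channel: the cleaned signal is tiled into consecutive 0.25-s windows
(windows never straddle epoch boundaries), the absolute Pearson
correlation between every window pair forms a recurrence matrix, all
channels' matrices are binarized at one shared threshold (the median of
the pooled off-diagonal entries), and the Shannon entropy of the
distribution of diagonal line lengths (runs of recurrent window pairs,
length >= 2, line of identity excluded) quantifies how diversely brain
states recur over time.  The DMN summary is the median entropy over the
channels whose air-baseline entropy exceeds 1 bit — a channel set that in
the source analyses overlays the medial default-mode network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from qeeg.io import StudyConfig, logger
from qeeg.preprocess import EpochSet


@dataclass
class RecurrenceMatrix:
    """Absolute window cross-correlations in [0, 1] with unit diagonal."""

    r: np.ndarray
    window: float
    channel: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        n = r.shape[0]
        if r.shape != (n, n):
            raise ValueError("recurrence matrix must be square")
        self.r = r

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.r.shape[0], k=1)
        return self.r[iu]


@dataclass
class ComplexityMap:
    """Per-channel recurrence entropy plus the baseline-defined DMN mask."""

    entropy: np.ndarray
    channel_labels: tuple[str, ...]
    dmn_mask: np.ndarray | None = None
    dmn_complexity: float | None = None


def _windows(ep: EpochSet, channel: int, window: float) -> np.ndarray:
    """Tile one channel into consecutive non-overlapping windows.

    Windows respect epoch boundaries: each epoch is tiled separately and
    the window stacks concatenated, so no window mixes discontinuous data.
    """
    w = int(round(window * ep.fs))
    if abs(w - window * ep.fs) > 1e-9:
        raise ValueError("window length must be an integer number of samples")
    per_epoch = ep.n_samples // w
    if per_epoch * ep.n_epochs < 2:
        raise ValueError("need at least 2 windows")
    x = ep.epochs[:, channel, : per_epoch * w]
    return x.reshape(ep.n_epochs * per_epoch, w)


def recurrence_matrix(
    series: np.ndarray, fs: float, window: float = 0.25, channel: str = ""
) -> RecurrenceMatrix:
    """Absolute correlation between all pairs of consecutive windows.

    ``series`` is either a 1-D signal (tiled directly) or a pre-tiled
    ``[n_windows, window_samples]`` stack.  Zero-variance windows get zero
    correlation with everything (warned), and the diagonal is set to 1.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        w = int(round(window * fs))
        if abs(w - window * fs) > 1e-9:
            raise ValueError("fs * window must be integral")
        n_win = len(x) // w
        if n_win < 2:
            raise ValueError("series shorter than 2 windows")
        x = x[: n_win * w].reshape(n_win, w)
    r = _abs_corr(x)
    return RecurrenceMatrix(r=r, window=window, channel=channel)


def _abs_corr(win: np.ndarray) -> np.ndarray:
    """|Pearson r| between all window pairs; zero-variance rows -> 0."""
    centred = win - win.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    bad = norms == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} constant windows: correlations set to 0",
            stacklevel=2,
        )
    safe = np.where(bad, 1.0, norms)
    unit = centred / safe[:, None]
    r = np.abs(unit @ unit.T)
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, 0.0, 1.0)


def recurrence_matrices(ep: EpochSet, cfg: StudyConfig | None = None) -> list[RecurrenceMatrix]:
    """Per-channel recurrence matrices for a cleaned epoch set."""
    cfg = cfg or StudyConfig()
    out = []
    for c, lab in enumerate(ep.channel_labels):
        win = _windows(ep, c, cfg.rqa_window)
        out.append(RecurrenceMatrix(r=_abs_corr(win), window=cfg.rqa_window, channel=lab))
    return out


def binarize_recurrence(mats: list[RecurrenceMatrix]) -> tuple[list[np.ndarray], float]:
    """Binarize every channel's matrix at one shared threshold.

    The threshold is the median of the pooled off-diagonal entries of all
    channels' matrices for this recording; an entry becomes 1 iff it is
    >= the threshold.  Returns the binary matrices and the threshold.
    """
    if not mats:
        raise ValueError("no recurrence matrices")
    shapes = {m.r.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError("recurrence matrices differ in shape")
    pooled = np.concatenate([m.offdiag() for m in mats])
    if pooled.size == 0:
        raise ValueError("empty off-diagonal pool")
    threshold = float(np.median(pooled))
    binary = [(m.r >= threshold).astype(np.uint8) for m in mats]
    return binary, threshold


def diagonal_entropy(b: np.ndarray, l_min: int = 2) -> float:
    """Shannon entropy (bits) of the diagonal line-length distribution.

    Maximal runs of 1s are enumerated along every diagonal except the line
    of identity; runs shorter than ``l_min`` are ignored.  Returns 0 when
    no qualifying line exists.
    """
    b = np.asarray(b)
    n = b.shape[0]
    if b.shape != (n, n):
        raise ValueError("binary matrix must be square")
    counts: dict[int, int] = {}
    for k in range(-(n - 1), n):
        if k == 0:
            continue
        d = np.diagonal(b, offset=k).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], d, [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            length = int(stop - start)
            if length >= l_min:
                counts[length] = counts.get(length, 0) + 1
    if not counts:
        return 0.0
    c = np.array(list(counts.values()), dtype=float)
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def channel_complexity(ep: EpochSet, cfg: StudyConfig | None = None) -> ComplexityMap:
    """Per-channel recurrence entropy for one cleaned recording."""
    cfg = cfg or StudyConfig()
    mats = recurrence_matrices(ep, cfg)
    binary, threshold = binarize_recurrence(mats)
    if not cfg.rqa_all_pairs:
        binary = [_consecutive_band(b) for b in binary]
    ent = np.array([diagonal_entropy(b, cfg.rqa_l_min) for b in binary])
    logger.debug("complexity: threshold %.3f, entropy median %.3f bits",
                 threshold, float(np.median(ent)))
    return ComplexityMap(entropy=ent, channel_labels=ep.channel_labels)


def _consecutive_band(b: np.ndarray) -> np.ndarray:
    """Keep only the first off-diagonals (consecutive-window reading)."""
    out = np.zeros_like(b)
    n = b.shape[0]
    idx = np.arange(n - 1)
    out[idx, idx + 1] = b[idx, idx + 1]
    out[idx + 1, idx] = b[idx + 1, idx]
    np.fill_diagonal(out, b.diagonal())
    return out


def dmn_complexity(
    maps: dict[str, ComplexityMap],
    baseline_key: str = "air_baseline",
    entropy_threshold: float = 1.0,
) -> dict[str, ComplexityMap]:
    """Apply the baseline-derived DMN mask to every exposure's map.

    The mask is the channel set whose baseline entropy exceeds
    ``entropy_threshold`` bits, fixed per participant; each exposure's DMN
    complexity is the median entropy over that mask.  An empty mask is an
    error (the participant is excluded upstream).
    """
    if baseline_key not in maps:
        raise KeyError(f"baseline map {baseline_key!r} missing")
    base = maps[baseline_key]
    mask = base.entropy > entropy_threshold
    if not mask.any():
        raise ValueError("empty DMN mask: no channel above threshold at baseline")
    out = {}
    for key, cmap in maps.items():
        if cmap.entropy.shape != base.entropy.shape:
            raise ValueError("exposure map shape differs from baseline")
        out[key] = ComplexityMap(
            entropy=cmap.entropy,
            channel_labels=cmap.channel_labels,
            dmn_mask=mask.copy(),
            dmn_complexity=float(np.median(cmap.entropy[mask])),
        )
    return out
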