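"""Frequency power per electrode: Hanning-taper spectra and band averages.

Power is estimated per 2-s epoch with a single Hanning taper on an integer
1-100 Hz grid and averaged over epochs.  Band averages use half-open
``[lo, hi)`` edges so the shared edges of the canonical bands (4, 8, 14 Hz)
are counted once, in the upper band, and are reported in dB re 1 uV^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from qeeg.preprocess import EpochSet

FREQ_GRID = np.arange(1.0, 101.0)  # 1..100 Hz inclusive, 1 Hz step


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.lo < self.hi <= 100.0):
            raise ValueError(f"band {self.name} must satisfy 1 <= lo < hi <= 100")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 30.0),
)


def power_spectrum(ep: EpochSet) -> np.ndarray:
    """Hanning-tapered power on the 1-100 Hz integer grid, epoch-averaged.

    Returns ``[n_channels, 100]`` mean power (uV^2/Hz density scaling).
    The epoch length sets the native frequency resolution; power at the
    integer grid frequencies is taken from the matching FFT bins.
    """
    if ep.n_epochs < 1:
        raise ValueError("empty epoch set")
    if ep.fs < 200.0:
        raise ValueError("sampling rate below 200 Hz cannot reach 100 Hz")
    freqs, psd = signal.periodogram(
        ep.epochs, fs=ep.fs, window="hann", axis=-1
    )
    # map each grid frequency to its FFT bin (grid is a subset of the bins
    # whenever epoch_length is a whole number of seconds)
    idx = np.searchsorted(freqs, FREQ_GRID)
    if not np.allclose(freqs[idx], FREQ_GRID, atol=1e-6):
        raise ValueError("1 Hz grid not representable at this epoch length")
    return psd[..., idx].mean(axis=0)


def band_power(
    spectrum: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    channel_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Average band power in dB re 1 uV^2.

    Per band, the mean of the grid bins with ``lo <= f < hi`` is taken and
    converted as ``10*log10(power)``.  Returns a channels x bands frame.
    """
    spectrum = np.atleast_2d(np.asarray(spectrum, dtype=float))
    out = {}
    for band in bands:
        sel = (FREQ_GRID >= band.lo) & (FREQ_GRID < band.hi)
        if not sel.any():
            raise ValueError(f"band {band.name} covers no grid bins")
        mean_power = spectrum[:, sel].mean(axis=1)
        with np.errstate(divide="ignore"):
            out[band.name] = 10.0 * np.log10(mean_power)
    index = channel_labels if channel_labels is not None else range(spectrum.shape[0])
    return pd.DataFrame(out, index=index)


def band_power_map(ep: EpochSet, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> pd.DataFrame:
    """power_spectrum -> band_power with the epoch set's channel labels."""
    return band_power(power_spectrum(ep), bands, channel_labels=ep.channel_labels)
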