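"""Core data model, EDF/BDF I/O, and study configuration.

Recordings live in memory as microvolt ``float64`` matrices with their
montage metadata.  On disk the native container is 24-bit BDF (the BioSemi
acquisition format); EDF is accepted on read.  Reading goes through MNE's
EDF/BDF reader; the BDF writer here is a minimal deterministic encoder
whose output round-trips through that reader within container quantization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from qeeg.layout import ChannelLayout, canonical_label, default_layout

logger = logging.getLogger("qeeg")

EXPOSURES: tuple[str, ...] = ("air_baseline", "O2_101", "O2_142", "O2_284")
#: The three hyperoxic exposures compared against the air baseline.
O2_EXPOSURES: tuple[str, ...] = ("O2_101", "O2_142", "O2_284")
CONDITIONS: tuple[str, ...] = ("eyes_open", "eyes_closed")

_DIG_MIN, _DIG_MAX = -8388608, 8388607  # 24-bit signed


class FormatError(ValueError):
    """Unreadable or malformed on-disk container."""


class LayoutError(ValueError):
    """Channel set of a file cannot be resolved against the layout."""


@dataclass
class Recording:
    """One participant/exposure/condition multichannel time series.

    ``data`` is ``[n_channels, n_samples]`` in microvolts, channel order
    following ``layout.labels``.
    """

    data: np.ndarray
    fs: float
    layout: ChannelLayout
    participant_id: str = "unknown"
    exposure: str = "air_baseline"
    condition: str = "eyes_open"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [n_channels, n_samples]")
        if self.data.shape[0] != len(self.layout):
            raise ValueError(
                f"{self.data.shape[0]} channels but layout has {len(self.layout)}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.exposure not in EXPOSURES:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def scalp_data(self) -> np.ndarray:
        return self.data[self.layout.scalp_indices()]

    def eog_data(self) -> np.ndarray:
        return self.data[self.layout.eog_indices()]

    def digest(self) -> str:
        """SHA-1 of the sample matrix, for provenance logging."""
        return hashlib.sha1(np.ascontiguousarray(self.data).tobytes()).hexdigest()[:12]


# --------------------------------------------------------------------------
# Study configuration
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """All printed analysis constants of the pipeline in one place.

    Defaults follow the study protocol: four bands partitioning 1-30 Hz,
    2-s epochs at a 256 Hz analysis rate, 50 Hz mains, quantitative
    artifact detectors, a 4-bin bias-corrected MI estimator on the alpha
    envelope, 0.25-s recurrence windows, and 1000-permutation cluster
    statistics at alpha = 0.05.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 14.0),
            "beta": (14.0, 30.0),
        }
    )
    epoch_length: float = 2.0
    resample_rate: float = 256.0
    line_freq: float = 50.0
    highpass: float = 1.0
    eog_r_max: float = 0.7
    hf_z_max: float = 3.0
    hf_band: tuple[float, float] = (105.0, 120.0)
    mi_bins: int = 4
    mi_bias_correction: bool = True
    mi_per_epoch: bool = False          # False: envelopes concatenated across epochs
    envelope_trim: float = 0.25         # s trimmed per epoch edge before MI
    binarize_fraction: float = 0.8      # threshold at min + frac * range of baseline
    rqa_window: float = 0.25
    rqa_l_min: int = 2
    rqa_all_pairs: bool = True          # full recurrence plot vs consecutive-only
    dmn_entropy_threshold: float = 1.0  # bits; baseline mask rule
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    family_size: int = 3                # Bonferroni family: O2 exposures vs baseline
    rt_ceiling: float = 5.0             # s, psychometric response ceiling
    rt_normalizer: str = "ceiling"      # or "observed_max"
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.resample_rate / 2.0
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi <= nyq):
                raise ValueError(f"band {name} outside (0, Nyquist]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("permutation count must be >= 100")
        if self.hf_band[1] >= nyq:
            raise ValueError("high-frequency detector band must lie below Nyquist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        if "hf_band" in raw:
            raw["hf_band"] = tuple(raw["hf_band"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        d["hf_band"] = list(d["hf_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# --------------------------------------------------------------------------
# BDF writer / EDF-BDF reader
# --------------------------------------------------------------------------

def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a 24-bit BDF file.

    Data records are 1 s long, so trailing samples beyond a whole second
    are dropped (analysis durations are whole seconds).  Physical ranges
    are per-channel integer microvolt bounds, making the encoder
    deterministic: identical recordings produce byte-identical files.
    Participant/exposure/condition metadata is stored in the recording-id
    header field.
    """
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("BDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s data record")
    data = rec.data[:, : n_rec * fs]
    n_ch = rec.n_channels

    pmin = np.floor(data.min(axis=1)).astype(np.int64) - 1
    pmax = np.ceil(data.max(axis=1)).astype(np.int64) + 1

    hdr = bytearray()
    hdr += b"\xffBIOSEMI"
    hdr += _field("", 80)
    hdr += _field(f"qeeg {rec.participant_id} {rec.exposure} {rec.condition}", 80)
    hdr += b"01.01.00"
    hdr += b"00.00.00"
    hdr += _field(256 * (n_ch + 1), 8)
    hdr += _field("24BIT", 44)
    hdr += _field(n_rec, 8)
    hdr += _field(1, 8)
    hdr += _field(n_ch, 4)
    for lab in rec.layout.labels:
        hdr += _field(lab, 16)
    for _ in range(n_ch):
        hdr += _field("Active Electrode", 80)
    for _ in range(n_ch):
        hdr += _field("uV", 8)
    for v in pmin:
        hdr += _field(v, 8)
    for v in pmax:
        hdr += _field(v, 8)
    for _ in range(n_ch):
        hdr += _field(_DIG_MIN, 8)
    for _ in range(n_ch):
        hdr += _field(_DIG_MAX, 8)
    for _ in range(n_ch):
        hdr += _field("HP:DC; LP:none", 80)
    for _ in range(n_ch):
        hdr += _field(fs, 8)
    for _ in range(n_ch):
        hdr += _field("", 32)

    gain = (pmax - pmin).astype(np.float64) / (_DIG_MAX - _DIG_MIN)
    dig = np.round((data - pmin[:, None]) / gain[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype(np.int64)

    with open(path, "wb") as f:
        f.write(bytes(hdr))
        for r in range(n_rec):
            block = (dig[:, r * fs : (r + 1) * fs] & 0xFFFFFF).astype(np.uint32)
            raw = np.empty((n_ch, fs, 3), dtype=np.uint8)
            raw[..., 0] = block & 0xFF
            raw[..., 1] = (block >> 8) & 0xFF
            raw[..., 2] = (block >> 16) & 0xFF
            f.write(raw.tobytes())
    logger.info("wrote %s (%d ch, %d s, digest %s)", path.name, n_ch, n_rec, rec.digest())
    return path


def _parse_recording_id(rid: str) -> dict[str, str]:
    parts = rid.split()
    if len(parts) == 4 and parts[0] == "qeeg":
        return {
            "participant_id": parts[1],
            "exposure": parts[2],
            "condition": parts[3],
        }
    return {}


def read_recording(
    path: str | Path,
    layout: ChannelLayout | None = None,
    participant_id: str | None = None,
    exposure: str | None = None,
    condition: str | None = None,
) -> Recording:
    """Read an EDF or BDF file and align its channels to the layout.

    Channel names are resolved case-insensitively against the layout;
    channels that do not resolve (reference/status channels, extra leads)
    are dropped with a warning.  Fewer than the full scalp set is a
    ``LayoutError``.  Channel order in the file is irrelevant: output
    follows the layout order.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    layout = layout or default_layout()
    suffix = path.suffix.lower()
    try:
        if suffix == ".bdf":
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
        elif suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise FormatError(f"unsupported container {suffix!r}")
    except FormatError:
        raise
    except Exception as exc:  # mne raises a mix of OSError/ValueError
        raise FormatError(f"cannot read {path}: {exc}") from exc

    file_labels = [canonical_label(nm) for nm in raw.ch_names]
    index_of = {lab: i for i, lab in enumerate(file_labels)}
    unknown = [nm for nm in file_labels if nm not in layout.labels]
    if unknown:
        logger.warning("dropping unresolvable channels: %s", unknown)
    missing_scalp = [lab for lab in layout.scalp_labels if lab not in index_of]
    if missing_scalp:
        raise LayoutError(f"missing scalp channels: {missing_scalp}")

    data_v = raw.get_data()  # volts
    rows = []
    for lab in layout.labels:
        if lab in index_of:
            rows.append(data_v[index_of[lab]] * 1e6)
        else:  # absent EOG channel: zero-filled, flagged
            logger.warning("channel %s absent in %s; zero-filled", lab, path.name)
            rows.append(np.zeros(data_v.shape[1]))
    meta = _parse_recording_id(str(raw.info.get("description") or ""))
    if not meta:
        # mne stores the EDF recording id in info['meas_id'] inconsistently;
        # fall back to the raw header field
        try:
            with open(path, "rb") as f:
                f.seek(88)
                meta = _parse_recording_id(f.read(80).decode("ascii", "ignore").strip())
        except OSError:
            meta = {}
    return Recording(
        data=np.array(rows),
        fs=float(raw.info["sfreq"]),
        layout=layout,
        participant_id=participant_id or meta.get("participant_id", "unknown"),
        exposure=exposure or meta.get("exposure", "air_baseline"),
        condition=condition or meta.get("condition", "eyes_open"),
    )
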