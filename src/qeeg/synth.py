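"""Synthetic multichannel-EEG study generator with injectable effects.

Emulates the signal properties the downstream metrics measure, without any
biophysical head modelling:

* band-limited oscillations per channel (delta/theta/alpha/beta), riding on
  1/f pink background noise;
* the alpha oscillator carries a controllable amplitude envelope
  ``kappa * shared + (1 - kappa) * private`` — ``kappa`` is the
  inter-channel envelope-coupling fraction that drives the
  mutual-information / global-efficiency axis;
* a hidden semi-Markov state sequence (gamma-distributed dwell times)
  switches the spectral gain pattern of the oscillators, so windows in the
  same state recur; the dispersion (CV) of the dwell times is the knob
  that drives the recurrence-entropy (DMN complexity) axis;
* blink templates on the EOG leads, mirrored attenuated into frontal scalp
  channels, and 80+ Hz EMG bursts on random channels, to exercise the
  artifact detectors;
* per-participant psychometric tables (20 items, log-normal reaction times
  truncated at the 5-s response ceiling, Bernoulli correctness).

Everything is deterministic given the study seed: recording-level streams
are derived with ``numpy.random.SeedSequence`` spawn keys, so any
participant/exposure/condition can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from qeeg.io import CONDITIONS, EXPOSURES, Recording
from qeeg.layout import ChannelLayout, default_layout
from qeeg.stats import PsychometricRecord

_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
}
# oscillator pass-bands sit inside the nominal bands, clear of the alpha
# edges: the analysis band-pass has finite roll-off, and state-modulated
# theta/beta power leaking through it would contaminate the alpha envelope
# with coupling the kappa parameter did not program
_OSC_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 2.8),
    "theta": (4.2, 6.5),
    "alpha": (8.0, 14.0),
    "beta": (18.0, 28.0),
}
_EXPOSURE_INDEX = {e: i for i, e in enumerate(EXPOSURES)}
_CONDITION_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

# frontal leakage weights of the blink template into scalp channels
_BLINK_LEAKAGE: dict[str, float] = {
    "Fp1": 0.45, "Fp2": 0.45, "AF3": 0.30, "AF4": 0.30,
    "F7": 0.15, "F3": 0.15, "F4": 0.15, "F8": 0.15, "Fz": 0.12,
}


@dataclass
class SyntheticStudyConfig:
    """Ground-truth parameters of a simulated exposure study.

    Per-exposure dictionaries default to a null study (identical
    parameters at every exposure); ``with_effects`` injects exposure
    effects relative to the baseline values.
    """

    n_participants: int = 12
    duration: float = 60.0            # s per condition
    fs: float = 1024.0
    conditions: tuple[str, ...] = CONDITIONS
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 3.0, "theta": 3.0, "alpha": 12.0, "beta": 2.5}
    )  # uV RMS scale per band
    kappa: dict[str, float] = field(
        default_factory=lambda: {e: 0.5 for e in EXPOSURES}
    )  # alpha envelope coupling per exposure
    n_states: int = 3
    dwell_mean: float = 1.0           # s
    dwell_cv: dict[str, float] = field(
        default_factory=lambda: {e: 1.2 for e in EXPOSURES}
    )  # dwell-time dispersion (coefficient of variation) per exposure
    state_gain_contrast: float = 2.0  # dominant-band weight of each state
    state_smoothing: float = 0.1      # s, gain cross-fade at state switches
    phase_diffusion: float = 0.4      # rad / sqrt(s) alpha carrier phase drift
    noise_rms: float = 4.0            # uV pink background
    blink_rate: float = 4.0           # events / min
    emg_rate: float = 1.0             # bursts / min
    blink_amplitude: float = 300.0    # uV on the EOG leads
    emg_amplitude: float = 25.0       # uV RMS within a burst
    rt_median: float = 1.5            # s, psychometric log-normal median
    rt_sigma: float = 0.35            # log-space SD
    p_correct: float = 0.9
    rt_scale: dict[str, float] = field(
        default_factory=lambda: {e: 1.0 for e in EXPOSURES}
    )  # multiplicative RT effect per exposure
    seed: int = 0

    def __post_init__(self) -> None:
        for e, k in self.kappa.items():
            if not (0.0 <= k <= 1.0):
                raise ValueError(f"kappa[{e}] must lie in [0, 1]")
        if self.dwell_mean <= 0.25:
            raise ValueError("dwell mean must exceed the 0.25-s recurrence window")
        for rate in (self.blink_rate, self.emg_rate):
            if rate < 0:
                raise ValueError("artifact rates must be >= 0")
        if self.n_states < 2:
            raise ValueError("need at least 2 hidden states")
        if self.duration < 2 * self.n_states * self.dwell_mean:
            raise ValueError(
                "duration too short for at least one dwell of every state"
            )

    def with_effects(
        self,
        delta_kappa: dict[str, float] | None = None,
        delta_dwell_cv: dict[str, float] | None = None,
        rt_scale: dict[str, float] | None = None,
        **overrides,
    ) -> "SyntheticStudyConfig":
        """Copy with additive exposure effects on kappa and dwell CV."""
        d = dataclasses.asdict(self)
        d.update(overrides)
        cfg = SyntheticStudyConfig(**d)
        for e, dk in (delta_kappa or {}).items():
            cfg.kappa[e] = float(np.clip(cfg.kappa[e] + dk, 0.0, 1.0))
        for e, dc in (delta_dwell_cv or {}).items():
            cfg.dwell_cv[e] = max(cfg.dwell_cv[e] + dc, 0.05)
        for e, s in (rt_scale or {}).items():
            cfg.rt_scale[e] = s
        return cfg


@dataclass
class GroundTruth:
    """Realized latent variables of one simulated recording."""

    kappa: float
    dwell_cv: float
    dwell_times: np.ndarray        # s, realized dwell sequence
    state_labels: np.ndarray       # per-sample hidden state
    blink_times: np.ndarray        # s
    emg_times: np.ndarray          # s


@dataclass
class SyntheticStudy:
    """A full simulated study: recordings, ground truth, psychometrics."""

    config: SyntheticStudyConfig
    recordings: dict[tuple[str, str, str], Recording]
    ground_truth: dict[tuple[str, str, str], GroundTruth]
    psychometrics: list[PsychometricRecord]

    def participant_ids(self) -> list[str]:
        return sorted({k[0] for k in self.recordings})


def _rng_for(cfg: SyntheticStudyConfig, participant: int, exposure: str,
             condition: str) -> np.random.Generator:
    key = (
        participant,
        _EXPOSURE_INDEX[exposure],
        _CONDITION_INDEX[condition],
    )
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, 1) + key))


def _participant_rng(cfg: SyntheticStudyConfig, participant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, participant)))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nzf = freqs > 0
    scale[nzf] = 1.0 / np.sqrt(freqs[nzf])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _smooth_positive_envelope(rng: np.random.Generator, n: int, fs: float,
                              cutoff: float = 1.5) -> np.ndarray:
    """Smooth strictly positive process with unit median (log-normal)."""
    z = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    # pad on the scale of the filter's time constant: the default pad is
    # far too short for a sub-hertz low-pass and leaves huge edge swings
    padlen = min(n - 1, int(3 * fs / cutoff))
    s = signal.sosfiltfilt(sos, z, padlen=padlen)
    sd = s.std()
    if sd > 0:
        s = s / sd
    return np.exp(0.45 * np.clip(s, -4.0, 4.0))


def _state_sequence(rng: np.random.Generator, cfg: SyntheticStudyConfig,
                    dwell_cv: float, n_samples: int, fs: float,
                    dwell_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Semi-Markov hidden states: gamma dwell times, no self-transitions.

    The first ``n_states`` dwells visit every state once (random order) so
    short recordings still realize each state at least once.
    """
    shape = 1.0 / dwell_cv ** 2
    scale = dwell_mean * dwell_cv ** 2
    labels = np.empty(n_samples, dtype=np.int64)
    dwells: list[float] = []
    order = rng.permutation(cfg.n_states)
    pos = 0
    i = 0
    prev = -1
    while pos < n_samples:
        if i < cfg.n_states:
            state = int(order[i])
        else:
            candidates = [s for s in range(cfg.n_states) if s != prev]
            state = int(rng.choice(candidates))
        dwell = float(max(rng.gamma(shape, scale), 2.0 / fs))
        n_dwell = min(int(round(dwell * fs)), n_samples - pos)
        n_dwell = max(n_dwell, 1)
        labels[pos : pos + n_dwell] = state
        dwells.append(n_dwell / fs)
        pos += n_dwell
        prev = state
        i += 1
    if len(np.unique(labels)) < cfg.n_states:
        raise ValueError("duration too short for at least one dwell of every state")
    return labels, np.array(dwells)


def _blink_template(fs: float) -> np.ndarray:
    """300-ms biphasic transient: big positive lobe, smaller smooth rebound."""
    u = np.arange(int(round(0.3 * fs))) / round(0.3 * fs)
    g = np.sin(np.pi * u) ** 2 * (1.0 - 1.7 * u)
    return g / np.abs(g).max()


def simulate_recording(
    cfg: SyntheticStudyConfig,
    participant: int,
    exposure: str,
    condition: str = "eyes_open",
    layout: ChannelLayout | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic recording plus its latent ground truth.

    Scalp channels are a sum over bands of gain-modulated narrowband
    oscillators plus pink noise.  The hidden state sets which band
    dominates each moment (state-specific spectral gain pattern and
    state-specific alpha carrier frequency), so recurrence structure
    follows the dwell-time process.  The alpha oscillator is an
    amplitude-modulated constant-magnitude carrier, so its Hilbert
    envelope equals the programmed ``kappa``-coupled envelope process.
    """
    layout = layout or default_layout()
    if exposure not in EXPOSURES:
        raise ValueError(f"unknown exposure {exposure!r}")
    rng = _rng_for(cfg, participant, exposure, condition)
    p_rng = _participant_rng(cfg, participant)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    n_scalp = layout.n_scalp
    kappa = cfg.kappa[exposure]
    dwell_cv = cfg.dwell_cv[exposure]

    # ---- participant-stable structure ------------------------------------
    chan_gain = np.exp(0.15 * p_rng.standard_normal(n_scalp))
    dwell_mean = cfg.dwell_mean * float(np.exp(0.1 * p_rng.standard_normal()))
    band_names = list(_BANDS)
    # non-alpha bands: each state prefers one band (cycling), with a
    # per-channel spatial gain pattern; the alpha band is deliberately NOT
    # state-gain-modulated, so its envelope carries only the programmed
    # kappa coupling (states instead switch the alpha carrier frequency,
    # which recurrence sees but the envelope does not)
    non_alpha = [b for b in band_names if b != "alpha"]
    dominant = [non_alpha[s % len(non_alpha)] for s in range(cfg.n_states)]
    # state-specific alpha carrier frequencies (Hz): each channel gets its
    # own permutation of a grid kept away from the 8/14 Hz band edges.
    # A channel's mapping is what recurrence needs (same state -> same
    # carrier); sharing one mapping across channels would let the
    # band-pass filter's frequency-dependent gain convert the common
    # frequency track into a common amplitude modulation, i.e. envelope
    # coupling that kappa did not program.
    freq_grid = np.linspace(9.25, 12.75, cfg.n_states)
    alpha_freqs = np.stack([p_rng.permutation(freq_grid) for _ in range(n_scalp)])

    # ---- hidden states ----------------------------------------------------
    labels, dwells = _state_sequence(rng, cfg, dwell_cv, n, fs, dwell_mean)
    state_gain = np.full((cfg.n_states, len(band_names), n_scalp), 0.4)
    alpha_band_idx = band_names.index("alpha")
    state_gain[:, alpha_band_idx, :] = 1.0
    for s in range(cfg.n_states):
        bi = band_names.index(dominant[s])
        # state-specific spatial pattern over channels
        state_gain[s, bi, :] = cfg.state_gain_contrast * np.exp(
            0.3 * p_rng.standard_normal(n_scalp)
        )
    # cross-faded one-hot state indicators: abrupt gain steps would inject
    # broadband clicks that the muscle-artifact detector (correctly) flags
    indicator = np.zeros((n, cfg.n_states))
    indicator[np.arange(n), labels] = 1.0
    k = max(int(round(cfg.state_smoothing * fs)), 1)
    kernel = np.hanning(k + 2)[1:-1]
    kernel /= kernel.sum()
    for s in range(cfg.n_states):
        indicator[:, s] = np.convolve(indicator[:, s], kernel, mode="same")

    # ---- alpha oscillator with programmed envelope -------------------------
    # constant-magnitude carrier whose frequency is set by the hidden state
    # and whose phase drifts slowly, so windows within one state stay
    # mutually coherent (recurrence) while the Hilbert envelope equals the
    # kappa-coupled envelope process exactly
    shared = _smooth_positive_envelope(rng, n, fs)
    data = np.zeros((n_scalp, n))
    phase_step_sd = cfg.phase_diffusion / np.sqrt(fs)
    # small fixed per-channel detuning keeps the carriers mutually
    # incoherent: the surface-Laplacian re-reference mixes neighbouring
    # channels, and coherent carriers would let a neighbour's envelope
    # enter a channel's analytic amplitude as spurious coupling
    detune = p_rng.uniform(-0.3, 0.3, n_scalp)
    for ch in range(n_scalp):
        private = _smooth_positive_envelope(rng, n, fs)
        env = kappa * shared + (1.0 - kappa) * private
        # ramp the carrier frequency across state switches with the
        # cross-fade kernel: an instantaneous frequency step leaves a
        # broadband corner in the spectrum
        freq_t = np.convolve(alpha_freqs[ch][labels] + detune[ch], kernel,
                             mode="same")
        phase = 2.0 * np.pi * np.cumsum(freq_t) / fs \
            + np.cumsum(rng.standard_normal(n)) * phase_step_sd \
            + rng.uniform(0, 2 * np.pi)
        carrier = np.cos(phase)
        data[ch] = cfg.band_amplitudes["alpha"] * chan_gain[ch] * env * carrier

    # ---- other band oscillators: narrowband filtered noise -----------------
    for bi, name in enumerate(band_names):
        if name == "alpha":
            continue
        lo, hi = _OSC_BANDS[name]
        sos = signal.butter(3, (lo, hi), btype="bandpass", fs=fs, output="sos")
        osc = signal.sosfilt(sos, rng.standard_normal((n_scalp, n)), axis=1)
        rms = osc.std(axis=1, keepdims=True)
        osc = osc / np.where(rms > 0, rms, 1.0)
        gain_tc = indicator @ state_gain[:, bi, :]  # [n, n_scalp]
        data += cfg.band_amplitudes[name] * chan_gain[:, None] * gain_tc.T * osc

    # ---- pink background ----------------------------------------------------
    data += cfg.noise_rms * _pink_noise(rng, (n_scalp, n), fs)

    # ---- EOG channels and blinks -------------------------------------------
    eog = cfg.noise_rms * 0.5 * _pink_noise(rng, (2, n), fs)
    template = _blink_template(fs) * cfg.blink_amplitude
    n_blinks = rng.poisson(cfg.blink_rate * cfg.duration / 60.0)
    blink_times = np.sort(rng.uniform(0.0, cfg.duration - 0.35, size=n_blinks))
    scalp_labels = layout.scalp_labels
    for bt in blink_times:
        start = int(round(bt * fs))
        seg = slice(start, start + len(template))
        eog[0, seg] += template[: eog[0, seg].size]
        eog[1, seg] += 0.9 * template[: eog[1, seg].size]
        for lab, w in _BLINK_LEAKAGE.items():
            if lab in scalp_labels:
                ch = scalp_labels.index(lab)
                data[ch, seg] += w * template[: data[ch, seg].size]

    # ---- EMG bursts ----------------------------------------------------------
    n_bursts = rng.poisson(cfg.emg_rate * cfg.duration / 60.0)
    emg_times = np.sort(rng.uniform(0.0, cfg.duration - 0.6, size=n_bursts))
    hi_edge = min(150.0, 0.45 * fs)
    sos_emg = signal.butter(3, (80.0, hi_edge), btype="bandpass", fs=fs, output="sos")
    for et in emg_times:
        start = int(round(et * fs))
        length = int(round(0.5 * fs))
        seg = slice(start, min(start + length, n))
        burst = signal.sosfilt(sos_emg, rng.standard_normal(seg.stop - seg.start))
        sd = burst.std()
        if sd > 0:
            burst = burst / sd
        chans = rng.choice(n_scalp, size=rng.integers(2, 6), replace=False)
        window = np.hanning(seg.stop - seg.start)
        for ch in chans:
            data[ch, seg] += cfg.emg_amplitude * burst * window

    full = np.vstack([data, eog])
    rec = Recording(
        data=full,
        fs=fs,
        layout=layout,
        participant_id=f"p{participant:02d}",
        exposure=exposure,
        condition=condition,
    )
    gt = GroundTruth(
        kappa=kappa,
        dwell_cv=dwell_cv,
        dwell_times=dwells,
        state_labels=labels,
        blink_times=blink_times,
        emg_times=emg_times,
    )
    return rec, gt


def simulate_psychometrics(
    cfg: SyntheticStudyConfig, participant: int, exposure: str
) -> PsychometricRecord:
    """20-item psychometric table: truncated log-normal RTs + correctness."""
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 3, participant, _EXPOSURE_INDEX[exposure]))
    )
    scale = cfg.rt_scale[exposure]
    rts = np.exp(rng.normal(np.log(cfg.rt_median * scale), cfg.rt_sigma, size=20))
    correct = rng.random(20) < cfg.p_correct
    timed_out = rts > 5.0
    rts = np.where(timed_out, np.nan, rts)
    correct = np.where(timed_out, False, correct)
    return PsychometricRecord(
        participant_id=f"p{participant:02d}",
        exposure=exposure,
        reaction_times=rts,
        correct=correct,
    )


def simulate_study(
    cfg: SyntheticStudyConfig, layout: ChannelLayout | None = None
) -> SyntheticStudy:
    """Generate the full study: recordings for every participant, exposure
    and configured condition, plus psychometric tables."""
    layout = layout or default_layout()
    recordings: dict[tuple[str, str, str], Recording] = {}
    ground_truth: dict[tuple[str, str, str], GroundTruth] = {}
    psychometrics: list[PsychometricRecord] = []
    for p in range(cfg.n_participants):
        pid = f"p{p:02d}"
        for exposure in EXPOSURES:
            for condition in cfg.conditions:
                rec, gt = simulate_recording(cfg, p, exposure, condition, layout)
                recordings[(pid, exposure, condition)] = rec
                ground_truth[(pid, exposure, condition)] = gt
            psychometrics.append(simulate_psychometrics(cfg, p, exposure))
    return SyntheticStudy(
        config=cfg,
        recordings=recordings,
        ground_truth=ground_truth,
        psychometrics=psychometrics,
    )
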