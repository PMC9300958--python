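# Methods

`qeeg` implements a sensor-level quantitative-EEG analysis of a repeated-
measures breathing-gas study: each participant is recorded at an air
baseline and at three 100% oxygen exposures (101, 142, 284 kPa absolute),
and three headline metrics are compared against baseline within
participant.  Because no recordings from such studies are publicly
deposited, the package ships a synthetic study generator whose latent
parameters map one-to-one onto the pipeline's metrics, so every stage can
be validated by oracle equivalence, statistical calibration, and
parameter recovery.

## Data model and preprocessing

Recordings are 32-channel scalp EEG (BioSemi 10-10 montage) plus two
infra-orbital EOG leads, sampled at 1024 Hz, stored as 24-bit BDF.  The
cleaning chain is fully deterministic:

1. scalp channels re-referenced to the instantaneous scalp average (EOG
   leads bypass re-referencing);
2. per-channel mean and linear trend removal;
3. polyphase anti-aliased resampling to 256 Hz with linear-ramp edge
   padding (zero padding turns a non-zero onset into a step whose
   broadband splash would contaminate the first epoch);
4. zero-phase 1 Hz high-pass (4th-order Butterworth) and zero-phase
   notches at the mains frequency (default 50 Hz) and all harmonics below
   Nyquist;
5. segmentation into consecutive non-overlapping 2-s epochs, the trailing
   partial segment dropped.

Two quantitative detectors mark artifact epochs.  An epoch is rejected if
any scalp channel's |Pearson r| with either EOG lead exceeds
`eog_r_max = 0.7` (eye activity), or if the per-epoch worst-channel
105–120 Hz log band power exceeds `hf_z_max = 3.0` robust z-scores across
epochs (muscle bursts).  The high-frequency score uses a median/MAD
location-scale estimate — artifact epochs would otherwise inflate a
mean/SD scale enough to mask themselves — with the scale floored at 0.25
natural-log units, the intrinsic epoch-to-epoch variability of a
band-power mean over a few dozen spectral bins; without the floor, a
recording whose in-band power is almost perfectly stable would flag
ordinary fluctuations.  Both thresholds are conventions (no published
values exist for this chain) and are exposed in `StudyConfig`.
Interactive independent-component review is deliberately out of scope:
it cannot be made deterministic or testable.

## Band power

Per epoch, a single Hanning taper and the Fourier power at integer
frequencies 1–100 Hz; epochs averaged.  Band averages use half-open
`[lo, hi)` edges over delta 1–4, theta 4–8, alpha 8–14 and beta 14–30 Hz
so the shared edges count once (in the upper band), reported in
dB re 1 µV².

## Mutual-information global efficiency

The connectivity chain is: Hjorth surface-Laplacian re-reference (each
channel minus the mean of its spatial neighbours; neighbourhoods are the
pruned Delaunay triangulation of the 2-D montage, typically 3–6
neighbours); zero-phase 8–14 Hz band-pass and Hilbert amplitude envelope
per epoch; per-epoch edges trimmed by 0.25 s (zero-phase filter
transients) and envelopes concatenated across epochs; binned mutual
information for all 496 channel pairs.

MI uses `b = 4` equipopulated bins with the first-order
(Panzeri–Treves) bias correction and is clipped at zero.  Four bins is
the canonical configuration of the binned-MI toolboxes this estimator
follows; `b` is configurable.  Coarse binning lower-bounds the continuous
MI — at `b = 4` the discretization loss for a ρ = 0.9 Gaussian is
0.42 bits, at `b = 16` about 0.08 bits — so the estimator-correctness
check in `scripts/acceptance.py` runs at `b = 16`, where the loss sits
inside the check's tolerance.  For the pipeline this loss is immaterial:
every matrix is binarized against a same-participant baseline threshold,
which cancels monotone distortions of the MI scale.

Each participant's air-baseline matrix sets an individual threshold at
`min + 0.8 · (max − min)` of its off-diagonal entries ("80% of the
range"; the alternative reading 0.8·max is rejected because "range" is a
spread term).  The same threshold binarizes all of that participant's
exposures.  Global efficiency of the binary graph is the mean inverse
shortest-path length (1 for a complete graph, 0 for an edgeless one),
computed through networkx and cross-checked in the tests against an
independent Floyd–Warshall enumeration.

## DMN recurrence complexity

Per channel: the cleaned signal is tiled into consecutive 0.25-s windows
(windows never straddle epoch boundaries); the absolute Pearson
correlation between every window pair forms a recurrence matrix.  The
full pairwise matrix is used — diagonal-line statistics are only defined
on a full recurrence plot, so "consecutive" is read as "consecutively
tiled windows"; a strictly-consecutive mode (first off-diagonal only) is
available via `rqa_all_pairs=False` for comparison.  All channels of a
recording are binarized at one shared threshold, the median of the
pooled off-diagonal entries.  The channel's complexity is the Shannon
entropy (bits) of the distribution of diagonal line lengths: maximal
runs of 1s along every diagonal except the line of identity, counted for
`l ≥ l_min = 2` (a single recurrent point is not a line, the standard
RQA ENTR convention).

The DMN summary fixes, per participant, the set of channels whose
air-baseline entropy exceeds 1 bit (in the source analyses this set
overlays the medial default-mode network) and reports the median entropy
over that mask for every exposure.  The mask is defined per participant,
not from the group average; a participant with an empty mask is excluded
and logged.

## Group statistics

Paired comparisons (each oxygen exposure vs air baseline) first test the
differences for normality with a Lilliefors-corrected Kolmogorov–Smirnov
test (parameters are estimated from the data, matching what the major
statistics packages do); normal differences get a two-tailed paired
t-test reported as mean difference with 95% CI, otherwise a Wilcoxon
signed-rank test reported as median and range.  Bonferroni correction
uses the natural family of three baseline contrasts per metric
(configurable).

The spatiospectral cluster-based permutation test thresholds node-wise
dependent t-values two-tailed at p = 0.05, clusters suprathreshold nodes
of like sign under the adjacency "spatial neighbours at the same band ∪
same channel at adjacent bands", scores clusters by summed t, and builds
the null from the maximum |cluster mass| over 1000 participant-wise
sign flips — the correct exchangeable scheme for a paired design (label
swaps within participants), with the max statistic providing family-wise
control.  Cluster p-values use the (1 + count)/(N + 1) convention.
Cohen's d (mean difference over SD of differences) is averaged over the
nodes of each significant cluster.  The connectivity matrices enter this
test as per-channel nodal MI strength (mean off-diagonal MI per channel,
a single-"band" map): pair-space clustering has no natural adjacency at
the sensor level.

The psychometric-impairment score averages the ceiling-normalized mean
reaction time (answered items only, divided by the 5-s response ceiling;
an observed-max mode exists) and the error rate (wrong answers plus
timeouts over 20 items); it lives in [0, 1], with 1 by convention when
every item times out.

## Synthetic study generator

`simulate_study` produces 12 participants × 4 exposures × 2 eye
conditions of 34-channel recordings at 1024 Hz plus per-exposure
psychometric tables.  Each scalp channel is a sum of band-limited
oscillators and 1/f pink noise (4 µV RMS):

* **Alpha (the connectivity axis).**  A constant-magnitude carrier
  multiplied by the envelope `κ·shared + (1−κ)·private`, where both
  envelope processes are smooth positive log-normals (1.5 Hz bandwidth)
  and κ ∈ [0,1] is the per-exposure coupling fraction.  Because the
  carrier has unit modulus, the Hilbert envelope equals the programmed
  process exactly, and pairwise envelope MI is monotone in κ.  The
  carrier is an FM tone rather than filtered noise: filtered noise has
  its own random Rayleigh envelope, which would both dilute the
  programmed coupling and break the κ = 1 limit in which all channels
  share one envelope.
* **Hidden states (the complexity axis).**  A semi-Markov state sequence
  (default K = 3, no self-transitions, each state visited at least once)
  with gamma-distributed dwell times (mean 1 s, per-exposure coefficient
  of variation, default 1.2) switches (i) the per-channel spectral gain
  pattern of the non-alpha oscillators and (ii) the alpha carrier
  frequency, drawn per channel as a permutation of a grid spanning
  9.25–12.75 Hz.  Windows recorded in the same state are mutually
  coherent (the carrier phase drifts by only ~0.4 rad/√s), windows in
  different states are near-orthogonal over 0.25 s, so the recurrence
  plot inherits the state sequence and the diagonal line-length spread
  inherits the dwell-time dispersion: higher CV → broader line-length
  distribution → higher entropy.
* Gain patterns and carrier frequencies cross-fade over 0.1 s at state
  switches; instantaneous switches would inject broadband clicks that
  the muscle detector (correctly) rejects.
* Frequency mappings are per channel and the carriers are mutually
  detuned (±0.3 Hz): a common frequency track would be converted by the
  band-pass filter's frequency-dependent gain into a common amplitude
  modulation — envelope coupling that κ did not program — and coherent
  carriers would leak neighbour envelopes through the Hjorth
  re-reference.  Similarly, the non-alpha oscillators occupy sub-bands
  held clear of the 8/14 Hz analysis edges (delta 1–2.8, theta 4.2–6.5,
  beta 18–28 Hz) so state-modulated power does not bleed through the
  filter skirts into the alpha envelope.
* **Artifacts.**  Blinks are smooth 300-ms biphasic transients (300 µV)
  on both EOG leads, mirrored into frontal channels with fixed
  attenuation weights (0.45 at Fp1/Fp2 down to 0.12 at Fz); EMG bursts
  are 0.5-s windows of 80–150 Hz noise (25 µV RMS) on 2–5 random
  channels.  Default rates are 4 blinks/min and 1 burst/min, sized so a
  60-s eyes-open recording loses a few of its 30 epochs, comparable to
  the attrition a human reviewer reports for resting-state data.
* **Psychometrics.**  20 reaction times per exposure, log-normal
  (median 1.5 s, σ_log 0.35) truncated at the 5-s ceiling (truncated
  items become timeouts), correctness Bernoulli(0.9); per-exposure
  multiplicative RT effects are injectable.

Exposure effects enter through `with_effects`, which adds per-exposure
deltas to κ and to the dwell-time CV.  All randomness derives from
`numpy.random.SeedSequence` spawn keys of the study seed, so identical
configurations are bit-identical and any recording can be regenerated in
isolation.

What the generator does **not** emulate: volume conduction and source
geometry, heteroscedastic channel noise, non-stationary artifact shapes,
alpha reactivity differences between eye conditions, or any physiological
link between gas pressure and the latent parameters.  Passing recovery
tests therefore demonstrate that the pipeline measures what its inputs
encode — not that real oxygen exposures behave like the generator.

## Validation and problem sizes

The test suite and `scripts/acceptance.py` validate the package at
reduced problem sizes chosen as the package's own trade-off between
statistical resolution and runtime:

* graph efficiency and diagonal-line entropy agree exactly with
  independent brute-force enumerations (100 random instances each);
* binned MI lands within 0.1 bit of the closed-form Gaussian value at
  b = 16, n = 10⁵ (ρ = 0.5 and 0.9) and within 0.02 bit of zero for
  independent data;
* the cluster test's family-wise error rate is measured over 300 null
  studies of Gaussian 32 × 4 maps at 200 permutations (the error-rate
  property belongs to the test, not to the EEG generator), and the
  Bonferroni-corrected paired test over 1000 null draws;
* connectivity recovery steps κ over (0.2, 0.4, 0.6, 0.8) across the
  four exposures (10 participants, 30-s recordings at 256 Hz) and
  requires monotone group-median efficiency; a constant-κ study must
  produce no significant efficiency contrast;
* complexity recovery runs 50 studies of 12 participants (40-s
  recordings at 256 Hz, baseline dwell CV 1.2 vs 0.3 at one oxygen
  exposure — a reduction sized to a ~0.18-bit group-mean DMN drop) and
  requires detection at Bonferroni-corrected p < 0.05 in ≥ 80% of
  studies while global efficiency stays non-significant: the
  connectivity/complexity dissociation that motivates carrying both
  metrics;
* two full directory-level runs with one seed must serialize
  byte-identically.

Synthetic recordings for these runs are generated directly at 256 Hz;
the generator's sampling rate only sets the bandwidth available to the
oscillators, all of which live below 30 Hz.

## Numerical choices and degenerate inputs

* Constant series: MI returns 0 with a warning (equipopulated bins are
  undefined); zero-variance recurrence windows correlate 0 with
  everything; a degenerate baseline matrix (max = min) refuses to
  binarize.
* Paired differences that are exactly constant short-circuit the t-test:
  p = 1 for all-zero differences, p = 0 for a constant non-zero shift.
* Empty DMN mask (no baseline channel above 1 bit) excludes the
  participant with a logged reason rather than propagating a NaN.
* The BDF writer stores integer-µV physical bounds per channel, making
  files byte-deterministic; round-trip error is bounded by the 24-bit
  quantization step.
* `sosfiltfilt` pad lengths are set from the filter's time constant
  where the default would be too short (sub-hertz envelope smoothing).

## Known limitations

* Sensor-space only; no source localization, no anatomical claim is
  attached to the DMN channel mask beyond its baseline-entropy
  definition.
* The MI estimator's absolute scale depends on bin count and envelope
  autocorrelation; only baseline-relative, within-participant contrasts
  are interpreted.
* ICA-based artifact removal is not reproduced; recordings dominated by
  non-blink, non-EMG artifacts would need manual review upstream.
* The permutation test's participant-order invariance is exact for the
  observed statistics and holds to Monte-Carlo error for p-values (the
  sign-flip draws attach to participant positions).
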