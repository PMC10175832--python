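# Methods

This note documents what each estimator computes, the parameters that
matter, the numerical conventions, and what the synthetic ground-truth
sessions do and do not emulate.

## Data model and preprocessing

A `Recording` holds a channel × sample matrix in microvolts with a common
sampling rate. EEG channels are the 19 electrodes of the international
10/20 montage (T7/T8/P7/P8 synonyms are normalized to T3/T4/T5/T6 at read
time); anything matching ECG/EKG is the cardiac channel and is excluded
from every EEG-only operation. Midline electrodes (Fz, Cz, Pz) stay in the
data model but are excluded from topographic and hemispheric summaries;
hemisphere assignment is by 10/20 label parity (odd = left, even = right).

*Average re-reference.* Each EEG channel has the instantaneous mean over
all EEG channels subtracted, leaving an exactly zero-mean montage. The
operation is a linear projection: applied to an already zero-mean montage
it changes nothing, and re-applying it is refused rather than silently
absorbed. A caveat that matters for interpretation: with few strong
sources, the common average itself becomes a shared component and can
manufacture coherence between electrodes that share nothing. The reference
synthetic session therefore gives every electrode a realistic baseline
gamma floor (~0.5–1 µV) so the common-average term stays small relative to
per-channel gamma noise.

*Notch.* Second-order IIR notches (Q = 30) at the mains frequency and each
harmonic below Nyquist (60, 120, 180, 240 Hz at 512 Hz), applied
forward–backward for zero phase. Measured on pure tones: ≥ 40 dB
attenuation at 60 Hz, ≤ 0.5 dB at 10 Hz. The ECG channel is skipped unless
requested.

*Bands.* delta [0, 4), theta [4, 8), alpha [8, 13), beta [13, 25), gamma1
[25, 55), gamma2 [80, 150) Hz. The 55–80 Hz gap is deliberate: it skirts
the mains region that the notch carves out. Band masks are half-open, so
the set tiles [0, 55) ∪ [80, 150) without overlap.

*Stages.* A stage table is an ordered list of non-overlapping labeled
intervals (S1 = baseline on full support, S2 = from ventilator withdrawal
to acute EEG suppression, later stages defined by cardiac features).
Explicit tables pass through verbatim; otherwise S2 is detected as the
span from the withdrawal annotation to the first time the 30-s moving RMS
of the broadband EEG falls below 25% of its baseline level. Both the
window and the fraction are configurable; stages beyond S2 always come
from explicit configuration, since their cardiac criteria vary per
recording.

## Spectral power

Spectrograms use 2-s Hann-tapered epochs with a 1-s hop, scaled as
one-sided power spectral density (µV²/Hz, taper power compensated), so the
density summed over frequency × bin width equals the signal variance — a
unit-amplitude tone integrates to 0.5 µV² within 5%. Band power integrates
the density over the band's [lo, hi) bins per epoch; the stage-level value
is the **median** over epochs (robust to brief transients, e.g. motion
during extubation), with the mean selectable where additivity matters.
Fold change between stages is the per-channel power ratio; denominators
can be floored at a configurable ε with the floored channels flagged in
the result. Power is stored linear; any log scaling is display-only.

## Phase-amplitude coupling

Phase and envelope come from zero-phase 4th-order Butterworth band-passes
followed by the analytic signal (order 2 proved insufficiently selective:
the comodulogram peak smeared into neighboring cells). One second is
trimmed from each end before binning to discard filter transients.

The modulation index bins phase into N = 18 equal bins over (−π, π],
averages the envelope per bin, normalizes the bin means to a distribution
P, and computes MI = (log N − H(P)) / log N. MI is invariant to envelope
rescaling and to constant phase offsets (up to binning granularity), 0 for
a phase-independent envelope, and 1 when all amplitude sits in one bin.
Empty phase bins get P = 0 with a warning rather than smoothing — at these
data sizes transparency beats imputation. An all-zero envelope is an
error.

Filter bandwidths: phase bands are 2 Hz wide below 20 Hz and 4 Hz above;
amplitude bands are at least 2.2× the phase frequency wide so the
side-bands at f_amp ± f_phase, which carry the modulation, pass the
envelope filter. Comodulogram grids default to 2–50 Hz (phase) × 8–256 Hz
(amplitude); cells whose amplitude band would overlap the phase band are
masked (NaN, not zero). Band-level PAC restricts the amplitude band to
gamma1/gamma2 — slow-on-fast nesting, not the reverse — and is computed in
30-s windows with a 15-s hop, summarized by the median; local mode couples
each electrode to itself, cross-regional mode couples prefrontal phase
(Fp1, F7, F3, Fp2, F4, F8) to posterior envelopes (C3, C4, T3, T4, T5, T6,
P3, P4, O1, O2).

*Surrogates.* Significance comes from circularly shifting the envelope by
uniform random offsets of at least 1 s (≥ 100 surrogates), which preserves
both series' spectra while destroying their alignment; the threshold is
the next-higher order statistic at the (1 − α) level — the exact
permutation-test convention; an interpolated quantile proved
anti-conservative (≈9% false positives at α = 0.05 instead of ≈5–6%). One
structural caveat: for *strictly periodic* coupled signals, a circular
shift merely rotates the preferred phase and leaves MI unchanged, so shift
surrogates have no power against pure-tone coupling. Real EEG phase
diffuses, which is what makes the surrogate family work; the test suite
exercises the high-z contract with aperiodic noise-carrier coupling for
exactly this reason.

## Coherence

Magnitude-squared coherence via Welch's averaged periodogram, 2-s Hann
segments with 50% overlap (matching the spectrogram granularity). At least
8 segments are required: a single-segment MSC is identically 1, and with K
segments independent signals sit at a bias floor near 1/K, which the tests
verify. Band-level values are the mean MSC over in-band bins; coherence is
analyzed only below 150 Hz. TPO-junction summaries average the three pair
values per hemisphere; long-range posterior–frontal pairs are tagged
contra/ipsi by hemisphere parity. Contrasts use classical Student t tests
(pooled variance unpaired, or paired), two-sided; the degenerate
zero-variance-equal-means case returns t = 0, p = 1 by convention.

## Directed connectivity (NSTE)

Signals are band-passed (zero-phase), then symbolized by ordinal patterns:
embedding dimension d = 3 (alphabet 3! = 6), delay τ of one quarter cycle
of the band center in samples, ties ranked earlier-index-smaller.
Transfer entropy uses plug-in joint frequencies of (y_{t+δ}, y_t, x_t)
with prediction horizon δ = τ. The normalized statistic subtracts the mean
TE of 20 source-shuffled surrogates (removing the finite-sample plug-in
bias) and divides by the plug-in conditional entropy H(y_{t+δ}|y_t),
clipping to [0, 1]. Rank-based symbols make the statistic exactly
invariant to affine rescaling of either input. Estimates with fewer than
10·(d!)² triples carry an undersampling warning; a constant target (zero
conditional entropy) is an error. Stage matrices evaluate every ordered
channel pair in 30-s windows (15-s hop, median summary); each pair's
shuffle stream is seeded from the pair identity, not the loop order, so
channel permutations commute with the computation exactly.
Feedforward/feedback summaries average posterior→frontal and
frontal→posterior entries between a TPO cluster (T5/P3/O1 or T6/P4/O2)
and the six prefrontal electrodes.

Calibration, measured by simulation: on unidirectionally coupled
gamma1-band pairs (unit gain, quarter-cycle lag, 12-s windows) the correct
direction wins in ≥ 95/100 seeds; independent pairs stay at or below 0.05.

## ECG chain

R peaks: the ECG is band-passed to 5–30 Hz and rectified; candidates are
local maxima above a variable threshold — half the rolling 2-s maximum,
floored at max(3 × MAD, 25% of the median rolling maximum) — with a 0.2-s
refractory period, then refined to the raw-ECG extremum within ±50 ms.
The second floor term exists because the first collapses to the noise
level inside long beat-free gaps, and spurious noise detections would mask
exactly the asystole events the pipeline must find. Flat or all-NaN input
yields an empty series; rates ≤ 60 Hz under-sample the QRS and are
rejected.

SDNN is the population standard deviation of all successive RR intervals,
with no ectopic-beat rejection: dying-heart rhythms are genuinely
irregular and NN-filtering would discard the signal of interest. Asystole
events are inter-peak gaps exceeding a threshold (default 3 s), reported
as (start, duration). The electrocardiomatrix stacks R-centered epochs
(default half-window 1.5 s, showing P-QRS-T plus neighboring beats) in
beat-time order; peaks without a complete window are dropped and counted.

## Synthetic sessions

The generator renders 19 EEG channels + ECG from a declarative spec:
per-stage, per-channel band RMS amplitudes on a 1/f background (power
∝ 1/f above 1 Hz, exponent configurable); PAC links as a slow tone plus a
fast tone whose envelope is 1 − χ + χ(1 + sin φ)/2 (χ = 0 decouples them);
coherent links as one shared band-limited noise component added to both
channels; directed links as a band-limited source added to the target
after a lag; and an ECG of Gaussian-derivative QRS templates (~40 ms,
1 mV) on a constant / ramped / Gaussian-jittered RR model. Asystole events
pin a beat to the event start and resume exactly at start + duration, so
the ground-truth RR gap equals the requested duration and detectors can be
held to a ±0.1 s recovery bound. All randomness flows through one seeded
generator per session; a fixed seed reproduces the output byte for byte.

The reference session (`default_session_spec`) encodes the study scenario
at desk scale — three 60-s stages at 512 Hz (clinical stages run minutes
to hours; 60 s gives every estimator its required window count while
keeping the full suite fast): S1 is a quiet-gamma comatose baseline with
posterior alpha; S2 raises gamma roughly five-fold in amplitude at
F7/F8/C3/C4, adds beta/gamma2 PAC at C4 (χ = 0.8) and gamma1-coherent
links across the left TPO triangle; S3 adds contralateral
posterior→frontal gamma1 directed links (T5→F4, P4→F7) and a 10-s
asystole. Under this design the preprocessed session shows ~15-fold gamma1
power rises, a > 10-fold C4 PAC rise, left > right TPO gamma1 coherence
(paired t across 10-s sub-windows, p < 0.05), and the injected links as
the NSTE argmax — the pattern the analysis exists to detect.

What the generator does **not** emulate: neural-mass dynamics, spikes,
burst-suppression morphology, volume conduction, electrode artifacts, EMG
contamination, or non-stationarity within a stage. Passing recovery tests
therefore demonstrates estimator correctness on signals with the assumed
statistical structure, not robustness to every pathology of clinical
scalp EEG.

## Numerical conventions and edge cases

- Tiny negative MI values from floating-point entropy are clipped to 0;
  MI is clipped to [0, 1].
- `fold_change` with a zero denominator is an error unless an ε floor is
  supplied; floored channels are flagged on the result.
- `contrast_ttest` returns (0, df, 1) for identical degenerate groups and
  ±inf with p = 0 when only the within-group variance vanishes.
- The EDF writer emits plain 16-bit EDF with 1-s records; non-whole-second
  recordings are padded with their final sample value (with a warning).
  EDF+ annotation import on read is delegated to MNE.
- Windowed analyses fall back to a single whole-interval window when the
  interval is shorter than the window length.

## Known limitations

- The deposited patient recordings this pipeline targets are an optional
  external benchmark; nothing in the test suite depends on them, and the
  per-patient stage criteria beyond S2 must be supplied as configuration.
- Shift surrogates are powerless against strictly periodic coupling (see
  above); for such signals use the z-score against an explicit null model
  instead.
- The plug-in TE estimator is biased upward at small sample counts; the
  shuffle correction removes most but not all of it, which is why NSTE
  values below ~0.05 should be treated as noise.
- Coherence and PAC are sensor-space quantities; no leakage correction or
  source modelling is attempted, and common-average leakage (see above)
  must be kept in mind when interpreting weak off-diagonal structure.
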