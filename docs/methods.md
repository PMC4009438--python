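# Methods

This note documents the signal models, parameter defaults and design
decisions of the `nirseeg` pipeline: what the synthetic data emulate, how
each processing stage works, and what the tests do and do not establish
about real recordings.

## Paradigm

A session is `n_samples` consecutive 60-s data samples. Each sample is

```
rest(5) tap(10) rest(5) mental(10) rest(5) tap'(10) rest(5) mental'(10)
```

so every sample contains one tapping trial per hand and one trial per
mental task, trials of the same modality separated by a 20-s gap (onsets
30 s apart). Subjects tap at 1 Hz — ten taps per trial — with the left hand
instructed to tap harder than the right so the two hands are separable by
response amplitude. Which hand and which mental task come first is not
fixed by the protocol; the package defaults to left hand and counting,
alternating within and across samples (`build_session` exposes both).

EEG analysis epochs span +1 to +11 s after each tapping prompt. NIRS
windows are shifted by the hemodynamic onset lag (2 s, the delay at which
HbO starts to rise after the prompt). Time is float seconds from session
start; blocks are half-open intervals `[onset, onset + duration)`.

## Synthetic data

The generator's purpose is to make every downstream stage testable with
exported ground truth. All shapes below are invented, config-driven
plumbing (`SimulationConfig`); none is fitted to real data.

**EEG.** Eight channels of unit-spectrum pink noise scaled to
`eeg_noise_std` = 2 µV. Each tap adds, on the contralateral motor channel
(left hand → C4, right hand → C3), a narrow transient spike (Gaussian,
σ = 20 ms) plus a β-burst (Gabor at 21 Hz, σ = 60 ms, 0.6× the spike
amplitude). Default amplitudes: 30 µV (left), 15 µV (right) — the 2:1
ratio realizes the harder-left-tap instruction. The other six channels
(T3/T4/P3/P4/F3/F4) carry only background noise and are stored but unused,
mirroring the recording montage's role.

**Hemodynamics.** Each mental block drives, per prefrontal channel, a
rise–plateau–washout HbO response: the neural drive starts `onset_lag`
(2 s) after the prompt and stops at block end; the response is a smoothstep
rise over `response_rise` (4 s), a plateau at `hbo_peak` (5 µM × channel
weight) until block end, then an exponential washout with time constant
`settle_time`/3, i.e. below 5 % of peak within the observed ~12-s settling
time. Two design points deserve emphasis:

* *Lag in the drive, not the kernel.* Convolving a stimulus boxcar with a
  response kernel whose support starts at the onset lag would keep the
  response rising for `lag` seconds **after** the block ends. In that world
  no causal detector can separate the first rest samples from activity, so
  the online Stop guarantee would be unattainable in principle. Placing the
  lag in the neural drive (subjects start late, stop on time) keeps both
  observed facts — the 2-s rise delay and the ~12-s settle — while letting
  the response peak at block end and only decay afterwards.
* *Washout shape.* The exponential tail is the conventional washout
  approximation and, unlike a flat-topped decay, pulls post-block rest
  windows quickly below the activity range. This is part of the generator
  calibration: amplitude/SNR defaults are chosen so the synthetic
  pipeline's accuracies land in the 80–95 % range a practitioner would
  expect from this architecture. They are tuning, not measurement.

Arithmetic and counting excite distinct spatial weight vectors across the
12 channels (linear ramps, anterior-left-heavy vs anterior-right-heavy) so
the two mental classes are separable; ΔHbR is a scaled negative copy of
ΔHbO (`hbr_peak` = −1.5 µM).

**Optics.** The forward model applies the modified Beer–Lambert law per
channel and wavelength, ΔA = (α_HbO·ΔcHbO + α_HbR·ΔcHbR)·l·d(λ), adds
sinusoidal physiological noise (cardiac 1.2 Hz — which aliases through the
1.81-Hz sampling, as it does on a real instrument of this rate —
respiratory 0.3 Hz, Mayer 0.1 Hz, random phases) and white measurement
noise in the ΔA domain, and emits I_out = I_in · exp(−A0 − ΔA_total).
Default extinction coefficients are standard compiled hemoglobin values at
760/830 nm (converted to natural-log, µM⁻¹cm⁻¹); l = 3 cm and d = 6.0 at
both wavelengths are typical adult-forehead values. All of these are
`OpticsConfig` fields; the simulator and the inverter must share one
config, which the tests enforce by round-trip (recovery to ≤ 1e-9 µM with
noise off).

## NIRS processing

`optical_density` references each channel/wavelength to its mean intensity
over a baseline interval (default: the initial 5-s rest block), which
cancels I_in, scattering loss and baseline absorbance. `mbll_invert`
divides each wavelength by l·d(λ) *before* inverting the 2×2 extinction
matrix — the published scalar form 1/(l·d(λ)) is ambiguous when the two
path-length factors differ, and per-wavelength division is the physically
consistent reading. A determinant below 1e-12 raises a configuration
error.

Denoising runs Gaussian low-pass first, wavelet shrinkage second (the
order is this package's choice; the two published steps are unordered).
The Gaussian kernel's −3 dB point equals the cutoff (default 0.1 Hz:
passes the ~0.017-Hz block-design fundamental, attenuates respiration and
cardiac bands); edges are reflect-padded, DC gain is exactly 1. Wavelet
shrinkage uses db5, level 4, soft universal threshold σ̂√(2 ln N) with σ̂
from the finest-level MAD; a zero threshold (noiseless input) is a no-op.
No stage changes series length or rate.

## EEG processing

Band-pass filtering is a causal order-4 Butterworth (12–30 Hz) — causal so
the identical filter can run online; zero-phase filtering is available
behind an explicit flag for offline use. The envelope is rectification
followed by a trailing 50-ms moving average (also causal). Tap detection
finds envelope peaks above `baseline mean + k·SD` (k = 2) with a
refractory distance of half a tap period. The SD in the threshold is the
rest-segment *signal* SD, not the envelope's own spread: the raw SD is a
stable noise scale that keeps the threshold far above the envelope's
sampling fluctuations, which makes the detected count reproducible
(exactly 10 taps per 10-s trial across seeds at the default SNR). Whether
"mean peak amplitude" means signed peaks or envelope magnitudes is
ambiguous in the protocol; this package uses envelope magnitudes. An epoch
with no detected peaks on a channel contributes 0 for that channel.

## Classifier

The two-class Fisher discriminant is implemented from scratch:
w = S⁻¹(μ₁ − μ₀) with pooled covariance (n − 2 denominator), ridge
ε = 1e-6·tr(S)/p added only when S is rank-deficient, and
b = −w·(μ₀+μ₁)/2 + log(π₁/π₀). Exact ties (w·x + b = 0) decode to class 0,
which is the rest/Stop class whenever one is present — no movement on
ambiguity. Cross-validation is seed-controlled stratified k-fold
(round-robin assignment within class after a seeded shuffle), reported in
percent. The published per-subject accuracies carry no train/test
protocol; stratified 5-fold over decision windows is this package's
documented default, and no attempt is made to reproduce those numbers
from synthetic data. scikit-learn's LDA serves as an independent oracle in
the test suite only.

## Fusion

Decisions are made at 1.81 Hz (the acquisition rate; the analysis text of
the source also prints 1.82 Hz, treated as a rounding inconsistency, and
its "new command every 0.6 s" as the ~0.55-s decision period of this grid;
the "processed at 250 Hz" remark carries no algorithmic content and is not
implemented). Per decision frame:

* **EEG state** — active if a supra-threshold envelope peak occurred within
  a trailing hold window (0.8 s: long enough to bridge a 1-Hz tap train,
  short enough that activity expires before the first decision frame of
  the following rest block). Active frames are subclassified left/right by
  an LDA on the (C3, C4) mean peak amplitudes in the window.
* **NIRS state** — active if the *recent rise* statistic exceeds its rest
  baseline by k·SD (and zero): the trailing difference over 2.76 s of the
  causally smoothed (1.7-s trailing average) channel-mean HbO, latched for
  1.1 s. A rise-based statistic rather than an amplitude threshold is what
  makes the Stop state reachable immediately after a mental block, when
  HbO is still elevated but falling. Active frames are subclassified
  arithmetic/counting by an LDA on the two prefrontal channel-group means.
* **Command** — the state pair maps through the rule table; simultaneous
  bimodal activity is impossible under the paradigm, so it maps to Stop
  with a logged conflict flag (a safety default of this implementation).
  The mapping of hands to Left/Right follows the rule table of the source
  (its abstract swaps them); a config switch exposes the alternative.

Baselines (EEG envelope mean and signal SD per channel, NIRS rise mean and
SD over rest frames) are estimated from the rest blocks of a calibration
session and carried in `TrainedModels`, so decoding is strictly causal:
truncating the input streams at time t changes no frame at or before t
(verified by test). The online path uses trailing moving averages instead
of the offline Gaussian/wavelet chain for the same reason.

## Evaluation

`evaluate_sessions` scores each simulated session like one subject: four
binary problems (Left/Right/Forward/Back vs Stop), EEG problems on the two
C3/C4 features, NIRS problems on the mean ΔHbO/ΔHbR features, stratified
5-fold CV per session and pooled. Per-block command accuracy uses a
decoder calibrated on a separate simulated session. The default batch (20
sessions of 5 samples) runs in a few seconds; the problem sizes were
chosen to keep the full test suite fast while leaving comfortable margins
on every statistical assertion. `aggregate_accuracies` reports mean and
sample SD (n − 1) per problem, display-rounded half-up to one decimal.

## What passing tests do and do not show

The simulator produces stylized, stationary signals: no motion artifacts,
eye blinks, electrode drift, superficial (scalp) hemodynamics, habituation
or attention drift, and its class geometry is by construction LDA-friendly.
Passing the suite therefore validates the *pipeline machinery* — timing,
unit bookkeeping, the optical inversion, causal feature extraction, the
classifier mathematics, and the fusion logic — not decoding performance on
real brains. The near-ceiling EEG accuracies on synthetic data should be
read as "the chain is lossless", not as a performance claim; published
accuracies for comparable human experiments sit in the 74–100 % range per
subject and problem.

## Known limitations

* The NIRS activity detector assumes the hemodynamic response stops rising
  by block end (guaranteed by the generator's drive model). Responses that
  peak after block end would add ~lag seconds of unavoidable post-block
  activity for any causal detector.
* The montage's 3×8 source–detector pairing is a documented plausible
  layout, not a reconstruction of the original headgear geometry.
* Single-channel-group spatial features summarize the 12 NIRS channels
  into two means; no per-channel spatial classifier is attempted.
* CytOx/water chromophores, short-separation regression, EDF/SNIRF
  interop and device I/O are out of scope.
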