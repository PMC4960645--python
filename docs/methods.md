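# Methods

This note documents the models, parameters and design choices behind
`seizlfp`, in the order the pipeline applies them, followed by the
simulator that generates its validation data and the known limitations
of both.

## Preprocessing

**Line-noise removal** estimates the amplitude and phase of each mains
component (50 and 60 Hz by default, first harmonic only unless asked
otherwise) by least-squares regression of cosine/sine terms over
overlapping 10 s windows with 50 % overlap, and subtracts the fitted
sinusoid with triangular cross-fading between windows. Windowing lets
the fit track slow drifts in line amplitude; cross-fading avoids edge
discontinuities; regression (rather than a recursive notch) avoids
ringing at the sharp event deflections the detector must preserve.
Subtraction is unconditional — when no line is present the fitted
amplitude is ≈ 0 and the trace passes through unchanged, so no
significance screen is needed. Removal runs at the native sampling
rate, before downsampling; this ordering is a convention of this
implementation.

**Downsampling** to the 1 kHz working rate uses polyphase filtering
with a Kaiser-windowed (β = 8) FIR low-pass and linear-trend edge
padding (`scipy.signal.resample_poly`). A sub-Nyquist sinusoid keeps
its amplitude to within 1 %; content above the new Nyquist is
attenuated by far more than 40 dB away from the trace edges.

**Z-scoring** (subtract the mean, divide by the SD of the entire
recording) is applied only on the spectral path. The population SD
(divide by n) is used; at the recording lengths involved (≥ 10⁵
samples) the difference from the sample SD is below 10⁻⁵ relative.
Event detection runs on the un-normalized mV trace so amplitudes stay
in physical units; because z-scoring is affine, the k·SD threshold
rule selects identical samples either way.

## Multitaper spectral estimation

Spectra are Thomson multitaper estimates: K = 5 unit-norm Slepian
(DPSS) tapers at time–bandwidth product NW = 3 (satisfying
K ≤ 2NW − 1), the one-sided power spectral density averaged over
tapers with equal weights (no adaptive weighting — simpler to verify,
and the standard default for these parameters). A "padding factor" of
−1 means no zero-padding: the FFT length equals the segment length,
giving a grid spacing of fs/n. With unit-norm tapers the PSD satisfies
Parseval's relation (Σ power · Δf ≈ signal variance; verified within
10 % on white noise), and forcing a single rectangular taper reproduces
the periodogram to 10⁻⁹, which is the estimator's oracle test.
Spectrograms evaluate full 2.5 s windows advancing by 50 ms from the
start of the trace; the slice count is ⌊(T − 2.5)/0.05⌋ + 1. Linear
power below 10⁻¹² is clamped before conversion to dB so silent traces
stay finite. Frequency-domain smoothing (when requested) is a centered
50-bin moving average with truncated edge windows and a matching
moving-SD envelope. Band power is the mean dB over grid frequencies
inside the band, both edges inclusive; the band-power change between
two caller-chosen periods is 100·10^((P₂−P₁)/10) % of baseline, with
identical periods allowed (trivially 100 %) but partial overlap
rejected.

## Event detection

The threshold is `baseline mean − 4·baseline SD`, with the baseline
the first 5 minutes of the recording (a warning is emitted if drug
application falls inside that window). Two guards that the threshold
rule alone does not determine are configuration-exposed with these
defaults:

* **minimum duration 5 ms** — a sub-threshold excursion must persist
  5 ms (5 samples at 1 kHz) to count, so single-sample noise cannot
  trigger;
* **merge window 100 ms** — supra-threshold runs separated by less
  than 100 ms merge into one event, so multi-lobed discharges count
  once. Both are an order of magnitude below the ~1 s inter-event
  intervals of interest.

Event time is the most negative sample of the (merged) run; amplitude
is baseline-mean-to-peak, a positive magnitude in mV (peak-to-peak is
deliberately not the default; the convention is stated rather than
inherited). Detection is invariant to constant offsets and scales
linearly with the trace. Onset and cessation are minutes from the
application marker to the first and last event; an event preceding
application yields a negative onset plus a warning flag rather than an
error. Histograms of pooled amplitudes and intervals use 40 uniform
bins spanning [min, max] with a right-inclusive last bin; an all-equal
input falls back to a single unit-width bin.

## LFP–ENG coupling

Each detected LFP event opens a ±100 ms window, truncated at the
midpoint between crowded events so windows stay disjoint. The 100 ms
half-width is a design choice sized against the ~1 s event intervals.
ENG screening is two-sided (|x − mean| > 4·SD of the ENG baseline)
because compound action potentials are biphasic, with a 2-sample
persistence requirement against single-sample noise. The cumulative
LFP count (1, 2, …, n) is correlated with the cumulative ENG count by
Pearson's r, and r² is reported together with the **matched fraction**
(mean of the per-window binaries). The fraction is reported because
the cumulative-count r² is insensitive to partial coupling — a strictly
alternating hit/miss sequence still has r² ≈ 1 — so a 1:1 claim needs
matched fraction ≈ 1, not just r² ≈ 1.

## Statistics

Welch's unpaired t-test (Welch–Satterthwaite fractional df), the
paired Student's t-test, and Pearson's correlation with its
t-transform p-value (df = n − 2) are implemented directly; all
p-values are two-sided, evaluated through the regularized incomplete
beta function `I_{df/(df+t²)}(df/2, 1/2)`, which matches scipy's t
distribution to 10⁻¹² and the textbook formulas to 10⁻¹⁰. A paired
test on differences with zero variance but nonzero mean returns an
infinite statistic with p = 0 and a degenerate flag; identical samples
raise instead. Under the null the Welch test's empirical type-I error
at α = 0.05 sits within [0.04, 0.06] (10,000 replicates).

## The simulator

`seizlfp.synth` generates paired LFP/ENG recordings with complete
ground truth. All randomness flows from one seeded PCG64 generator, so
(config, seed) determines every sample bit-exactly.

**Background.** 1/f-shaped broadband noise (flat below 0.5 Hz, 1/√f
roll-off to 100 Hz, steeper above, mirroring the 0.1–100 Hz analog
band-pass of typical LFP front-ends) plus a state oscillation:
band-limited Gaussian noise in 1–4 Hz for the anaesthetized state
(relative SD 1.0 against the broadband component) or 12–30 Hz for the
awake state (relative SD 0.7). Components are soft-saturated at 3–3.5
SD before mixing: physiological oscillations have characteristic
bounded amplitudes, not Gaussian tails, and without this bound the
background alone produces rare multi-second 4σ excursions that no
threshold detector could distinguish from events. The mixture is
rescaled so the overall SD equals `noise_sd_mv` (default 0.1 mV), which
puts the anaesthetized delta band ≥ 6 dB above the awake preset's.
Mains contamination is a fixed sinusoid (default 60 Hz, 0.05 mV,
random phase), and an optional application artifact adds a 3 mV
transient decaying over ~2 s.

**Event train.** Onset and cessation (minutes after application) are
truncated normals (≥ 0, cessation redrawn until it exceeds onset);
inter-event gaps are log-normal, moment-matched to the requested
mean ± SD — chosen over a normal because the awake condition
(0.83 ± 0.75 s) would otherwise produce negative gaps — and amplitudes
are truncated normals (> 0) with the first 15 % of the train ramped
linearly from 20 % to 100 % to emulate the gradual build-up. Each
event injects a biphasic waveform: a Gaussian negative lobe of depth
exactly `amp` (FWHM = half the 40 ms event width) followed by a 25 %
positive rebound one event-width later. The presets encode the
published group statistics per condition (amplitude 1.64 ± 0.67 mV and
interval 1.01 ± 0.88 s under anaesthesia, 1.4 ± 0.82 mV and
0.83 ± 0.75 s awake; onset/cessation 10.31 ± 5.1 / 32.83 ± 12.38 min
at 100 µM and 5.16 ± 3.41 / 47.50 ± 19.41 min at 250 µM), and the
control preset injects nothing.

**Seizure-state spectral change.** During the event span the
anaesthetized delta oscillation is suppressed to 30 % of its amplitude
and a beta-band component (relative SD 0.7) fades in, with 5 s ramps
at the span edges. This reproduces the reported direction of the band
change — delta below, beta above 100 % of baseline — on top of the
broadband power the event transients themselves add.

**ENG.** White noise (SD 0.02 mV) carrying, for each LFP event with
probability `couple_prob`, one biphasic 5 ms compound action potential
(0.5 mV, 25× the noise SD) at a truncated-normal latency (mean 20 ms,
jitter 10 ms, bounded to [0, 200] ms).

## Problem sizes

Preset defaults reflect the study's acquisition (10 kHz LFP, 2 kHz
ENG, recordings up to ~70 min). The test suite and the acceptance
script run the identical code paths at 1 kHz LFP with 10–30 min
recordings and 20 replicate seeds per condition — sizes at which the
group means of interest are estimated to ~1 % while the whole suite
runs in a few minutes.

## Limitations

* The simulator is phenomenological: no neural-mass or pharmacokinetic
  modelling, no movement artifacts beyond an optional step transient,
  no electrode drift. Passing tests demonstrate that the pipeline
  recovers what the generator injects under realistic noise, not that
  it is robust to every artifact of real recordings.
* The published group statistics used by the presets describe
  *detected* (supra-threshold) events. Using them as generating
  parameters means a few percent of simulated events fall below the
  4 SD threshold — noticeably for the awake condition, whose large
  amplitude SD (0.82 mV) leaves ~9 % of events sub-threshold, biasing
  recovered amplitude and interval means upward by ~10 %.
* Line-noise removal assumes a locally stationary line within each
  10 s window; rapidly frequency-wandering interference is out of
  scope.
* EDF input is not parsed; recordings arrive as columnar text or the
  package's binary container.
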