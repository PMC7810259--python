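# Methods

This note documents the models, conventions, and numerical choices behind
`modtrf`, and what the synthetic-data validation does and does not show.

## Stimulus synthesis

AM stimuli are built by inverse-FFT synthesis: a target modulation
*amplitude* spectrum is combined with phases drawn uniformly on [0, 2π) per
positive-frequency bin (conjugate symmetry keeps the time series real), and
inverse-transformed on a 10-s, 20-kHz grid. The 1/f family uses
amplitude ∝ f^(−χ) for χ ∈ {0.5, 0.75, 1, 1.5, 2}; the exponent is defined
on the amplitude spectrum, not the power spectrum. The DC bin is zeroed
before the inverse transform — a 1/f amplitude is singular at f = 0, and
the envelope mean is re-imposed anyway by depth normalization.

Each realization is conditioned with a high-pass Butterworth (order 3,
1 Hz) and a low-pass Butterworth (order 6, 30 Hz), applied forward only;
edge transients are discarded by keeping the middle 5 s of the 10-s
realization. The surviving segment is min/max-normalized so modulation
depth is exactly 100% (min 0, max 1). The envelope then multiplies a fresh
standard-normal white-noise carrier (one independent seed per stimulus),
50-ms raised-cosine on/off ramps are applied (first and last samples
exactly 0), and the waveform is scaled to a target digital RMS
(default 0.05 full scale — a stand-in for hardware SPL calibration, which
has no meaning in software).

The "speech" stimulus family uses a modulation spectrum estimated from
broadband speech envelopes: the rfft magnitudes of the reference envelopes
are averaged pointwise and resampled onto the synthesis grid. Because no
speech recording ships with the package, the default references are
synthetic surrogates (`make_speech_surrogate_envelopes`): random-phase
realizations of a 1/f^1.5 amplitude spectrum with a Gaussian emphasis at
4 Hz, the canonical syllabic-rate peak of connected speech. They are
labeled synthetic throughout; nothing about them reproduces any specific
recording.

Probe tones (1 kHz, 30 ms, 10-ms ramps) are *summed onto* half of the
stimuli at an onset drawn uniformly from [0.75, 4.25] s. The SNR convention
is global: mean-square tone power over its own 30 ms divided by the
long-term mean-square of the full 5-s masker equals 10^(−10/10). This makes
the global SNR identical across stimuli regardless of where the tone lands,
which is precisely what makes the *local* SNR informative.

## Cochlear acoustics

The cochlear front end is a 32-band gammatone filterbank (4th-order IIR,
`scipy.signal.gammatone`) with center frequencies log-spaced from 80 to
8000 Hz; band envelopes are Hilbert magnitudes, and the broadband envelope
is their unweighted mean (equal weighting is an assumption; nothing in the
construction favors any band).

### Recovering the 1/f exponent through the chain

The broadband gammatone envelope of modulated white noise is not the clean
AM envelope: it carries (i) an additive noise floor from the carrier's
intrinsic within-band envelope fluctuations, which buries the modulation
signal at high rates and *flattens* steep spectra, and (ii) the chain's
modulation transfer function (MTF) roll-off — narrow low-CF bands cannot
follow fast modulations — which *steepens* them. A naive log-log slope of
the measured spectrum is therefore biased in both directions at once
(for χ = 2 the raw chain slope reads ≈ 1.0).

`estimate_stimulus_exponent` removes both effects by measurement:

- **Floor**: for every stimulus, a matched control is synthesized from the
  *same carrier seed* with a constant envelope at the stimulus's envelope
  RMS, and its tapered power spectrum is subtracted in the power domain
  (independent components add in power). Pairing by carrier seed keeps the
  floor estimate correlated with the floor realization it removes.
- **MTF**: measured once with sinusoidally modulated white-noise probes
  (1–30 Hz, 100% depth), normalized at 1 Hz.
- **Fit**: the exponent is estimated by forward modeling — a candidate
  power law is passed through the conditioning filters' frequency response,
  the Hann taper's spectral smearing (computed exactly from the window
  transform), and the measured MTF, then binned exactly like the data; the
  best χ minimizes the inverse-variance-weighted squared error against the
  floor-subtracted bin powers over 2–20 Hz (12 log-spaced bins). Bins whose
  mean difference does not exceed twice its standard error are treated as
  below the floor and excluded. Forward modeling matters because Hann
  smearing alone inflates a 1/f^4 power spectrum near its 2-Hz edge enough
  to bias a naive slope by ≈ +0.1.

All spectral estimates demean first (the envelope's DC line otherwise leaks
into the 1–2 Hz bins) and use a Hann taper; a plain periodogram flattens a
χ = 2 spectrum to ≈ 1.6 through leakage alone.

### Local SNR

For probed stimuli, local SNR at window size w is
10·log10(tone power / masker power in the window), with the rectangular
window centered 15 ms after tone onset (mid-tone). Tone power is computed
from the analytically known ramped probe, not re-estimated from the
mixture; the masker is the probe-free waveform. Windows are clipped at
stimulus edges with a warning (the default onsets and windows never clip).
The nine window sizes are 30–500 ms.

## Behavior

Per AM type, a 2×2 confusion table over 60 trials yields
d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate). Two correction conventions are
implemented:

- `perfect_table` (default): only a fully perfect table (zero misses *and*
  zero false alarms) receives half an artificial incorrect trial in both
  error cells. A table perfect on one margin only leaves d′ undefined and
  raises — the caller must decide.
- `per_cell`: any empty cell gets the half trial, so d′ is always finite.
  The synthetic-observer pipeline uses this, because a simulated cohort
  reliably produces single-margin-perfect tables that a 19-participant
  human dataset would rarely show.

Correlations between d′ and local SNR are computed per participant across
the six AM types, Fisher z-transformed (|r| clipped at 1 − 1e−12 with a
warning), and only then averaged — averaging raw r first is a different,
rejected estimator, and a test asserts the order.

## EEG pipeline

Epochs are trials × channels × samples at 500 Hz, spanning −3 to +8 s
around stimulus onset. Preprocessing: average reference; zero-phase FIR
band-pass 1–45 Hz (Hamming-window design, order from the 3.3/Δf rule with a
1-Hz transition band, applied forward and reverse); baseline correction by
the −1 to 0 s mean. Trials containing NaNs are dropped with a log entry.
Artifact correction (ICA, visual rejection) is acquisition-side and not
modeled; synthetic data are clean.

The auditory component is the first principal component of the 0–500 ms
grand-average evoked response (channels × time, time points as
observations), unit-norm. Sign conventions are deterministic: the overall
sign makes the largest-magnitude weight positive, and polarity (±1) is
chosen so the mean component value 150–350 ms post-onset is positive —
automating the usual manual polarity check against the positive ~250-ms
evoked peak.

Band decomposition uses two-pass (zero-phase) Butterworth band-passes of
order 4: δ 1–3, θ 4–7, α 8–12, β 13–30, γ 31–45, full 1–45 Hz. Induced
power uses Morlet wavelets (1–45 Hz in 1-Hz steps, length rising linearly
from 2 to 10 cycles), trial-averaged, divided by the per-frequency mean of
the −1 to −0.75 s baseline and converted to dB; the induced power spectrum
averages 0.5–4.5 s to avoid onset/offset transients. Phase-sensitive
indices (evoked power, inter-trial coherence) are deliberately absent:
each stimulus has distinct modulation phases.

## TRF encoding

The forward model is response(t) = Σ_lag kernel(lag)·envelope(t − lag) + ε.
Kernels are estimated by ridge regression on a lagged design matrix,
kernel = (XᵀX + λM)⁻¹Xᵀy with M the identity except a zero at the intercept
position. The printed estimator in the source literature is written in a
backward-model (decoder) form while its reconstruction equation is forward;
this package implements the forward encoder consistently — a decoder is a
non-goal.

Conventions, applied identically at training and scoring time:

- envelopes are z-scored per trial and responses centered per trial
  (makes λ comparable across AM types);
- the intercept is unpenalized;
- trials are never concatenated — each trial's design is zero-padded at its
  own edges;
- **band matching**: before fitting, the envelope is filtered with the same
  zero-phase band-pass as the response. Filtering commutes with the
  convolutional forward model, so band-matching makes the estimated kernel
  comparable to the generating kernel; fitting a 1–45 Hz-filtered response
  on an unfiltered envelope estimates the *filtered* kernel instead, which
  for slowly modulated stimuli (χ ≥ 1.5) is badly distorted inside a
  0–500 ms lag window (validation r drops from ≥ 0.97 to ≈ 0.66);
- working rate 128 Hz (content ≤ 45 Hz; keeps XᵀX small), lag window
  0–500 ms, λ grid log-spaced 10⁻²–10⁶ (17 points) — none stated by the
  source analysis; all configurable.

λ is selected by cross-validation: leave-one-out over the 50 trials of an
AM type, or 10-fold over the ten 1-min segments of continuous material. The
selected model is refit on all trials; reported performance is the mean
*held-out* Fisher-z correlation at the selected λ. Cross-encoding applies a
trained model (with its λ — no re-selection on test data) to every other
type's trials, per-trial z averaged; the diagonal holds the own-type
held-out performance, an upper bound for transfer. Modulation-band-resolved
encoding filters envelopes into 2-Hz-wide bands over 1–45 Hz (order-2
two-pass Butterworth; 22 bands) and responses into the five neural bands
(order 4), repeating the CV per pair; cells whose filtered envelope falls
below 10⁻³ of the envelope's amplitude are reported missing rather than
scored.

## Permutation statistics

Condition labels are shuffled independently *within* each participant
(never across), 1000 times by default. Two summaries mirror the two uses:
`median_summary` (per-cell median across participants, then the mean of
medians — one global threshold) and `mean_summary` (per-cell means — one
threshold per cell from that cell's own permutation distribution).
One-sided thresholds are the ceil((1−α)·n_perm)-th order statistics —
conservative and exact at n_perm = 1000. Under an i.i.d. null the per-cell
flag rate at α = 0.05 is ≈ (n_perm·α rounded)/(n_perm+1) ≈ 0.0498 at
n_perm = 200, which the calibration check verifies against the exact
binomial interval.

## Synthetic data: what it emulates, and what it does not

`simulate_eeg` realizes exactly the forward model the analysis assumes:
component = Σ_bands conv(band-filtered envelope, kernel), channels =
topography × component + 1/f-amplitude Gaussian noise, epoched −3 to +8 s
at 500 Hz. Ground-truth kernels are difference-of-gamma biphasic shapes;
"shared" mode gives every AM type the same kernel (pairwise r = 1),
"specific" mode staggers peak latencies (60–290 ms) and widths so pairwise
correlations stay below 0.5. Response SNR is the variance ratio of the
noise-free component to the noise *projected onto the topography* over the
stimulus window. The topography is a smoothed random vector constrained to
the zero-mean channel subspace: average-referenced EEG only defines spatial
patterns up to the reference, so generating the truth outside that subspace
would cap PCA recovery for reasons unrelated to the estimator
(empirically |cos| ≈ 0.82 even without noise).

The behavioral observer reports the tone with probability
logistic((local SNR at the integration window − threshold)/slope) on probe
trials and a fixed false-alarm rate (0.1) on catch trials. Defaults:
integration window 30 ms, threshold −5 dB, slope 2 dB — a steep,
near-threshold psychometric function, chosen because detection in a
fluctuating masker is governed by whether the tone locally clears the
masker; the threshold sits well above the −10 dB global SNR because tones
are detected in envelope valleys. A shallower observer produces type-level
hit rates whose nonlinear aggregation (Φ⁻¹ of a mean logistic) distorts the
d′ profile toward longer-window SNR profiles and washes out the
short-window advantage.

Defaults reflect the emulated study: 50 trials per type enter the analysis,
0 dB response SNR, 32 channels (a mid-density montage; channel count only
scales simulation cost), 19 participants, noise spectral exponent 1. The
behavioral closure check uses a 200-participant simulated cohort: with 19
participants the per-window mean correlations differ by less than their
sampling error (the nine window profiles correlate at r > 0.94 across
types), so the check measures the generative model's expected profile, not
single-cohort luck — the same reasoning as the 1000-participant null
calibration.

What passing these checks shows: the pipeline is self-consistent — it
recovers what its own forward model generates, at realistic noise, trial
counts, and stimulus statistics. What it does not show: anything about
brains. Real EEG violates the model in known ways (non-stationary and
spatially correlated noise, multiple sources, nonlinear cochlear and
cortical processing, artifacts), so recovery numbers here are upper bounds
on what real recordings could yield.

## Known limitations

- The gammatone filterbank uses log-spaced center frequencies, not
  ERB-rate spacing, and no compressive nonlinearity.
- The exponent estimator assumes a power-law modulation spectrum; for the
  speech-like family, use `fit_exponent` on
  `modulation_spectrum_estimate` output instead (no floor subtraction).
- The speech-session surrogate is AM noise with a speech-like modulation
  spectrum; it shares no fine structure with real speech.
- `perfect_table` d′ correction can leave d′ undefined for single-margin-
  perfect tables by design; automated cohorts should use `per_cell`.
- Problem sizes in the validation suite (60 stimuli per type for spectra,
  50 trials per type for encoding, 200 permutation datasets of 10 × 6)
  are the package's chosen validation scale; estimates tighten with more.
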