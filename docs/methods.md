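# Methods

This note documents the models, estimators, defaults and numerical choices
behind `thetalink`, and what the synthetic-data validation does and does not
establish about real recordings.

## Signals and preprocessing

Recordings are two-channel LFP matrices (dHipp, PFC) with a sampling rate
and start time, stored in HDF5. Acquisition-rate data (e.g. 15 kHz,
0.1–300 Hz band) are downsampled to 1 kHz after an 8-pole Butterworth
anti-alias low-pass at 400 Hz applied forward-backward; all analysis bands
end at 48 Hz, so 1 kHz is lossless for these purposes. Loaders reject NaN
rather than imputing — gaps must be encoded as separate epochs. All times
are seconds from recording start; intervals are half-open [onset, offset).
Every config is hashable (SHA-256 of its canonical JSON) so derived outputs
can be traced to the exact parameters that produced them.

Band definitions: delta 1–4 Hz, theta 6–12 Hz, beta 20–30 Hz, low gamma
30–48 Hz. Capping gamma at 48 Hz keeps all bands clear of 50 Hz mains; a
notch filter is therefore off by default (a config flag exists).

## Multitaper estimation

Power spectra use Slepian (DPSS) tapers with unit energy. Defaults: 2-s
windows, 0.5-s step, time–bandwidth NW = 3, K = 5 tapers — a standard
multitaper operating point giving ±1.5 Hz smoothing and 0.5 Hz grid
resolution, adequate for a 6–12 Hz theta peak. Windows are demeaned
(constant detrend) before tapering. Densities are one-sided and scaled so
that the integral over [0, Nyquist] equals the signal variance; the suite
checks Parseval on white noise to 5%.

Band summaries report mean in-band power, peak power and peak frequency;
ties in peak power resolve to the lowest frequency. Time courses come from a
spectrogram (per-window PSDs on the window-center grid) averaged into
non-overlapping bins (10 s for 5-min sessions → 30 bins; 60 s for PAC → 5
bins); a trailing partial bin is dropped. The coefficient of variation of
per-2-s-bin peak frequency or peak power (sample SD / mean) quantifies the
stability of the theta oscillation.

Decision-zone epochs are the last 1.2 s before the animal exits the decision
zone in each T-maze phase. A 1.2-s epoch cannot support sliding-window
averaging, so it is analysed as a single window with a reduced taper family
(NW = 2, K = 3). Epochs shorter than 0.5 s are skipped with a warning.

When epochs of unequal length are pooled (exploration bouts, decision
windows mixed with long epochs), every tapered window is zero-padded onto
the standard 2-s frequency grid before pooling — the usual nfft-padding
device — so cross- and auto-spectra from short bouts enter the same estimate
with weight proportional to the windows they contribute.

## Coherence

Coherence is reported as *magnitude* coherence |C(f)| = |S_xy|/√(S_xx S_yy),
with cross- and auto-spectra averaged over windows × tapers before
normalization. This is stated explicitly because conventions differ; the
generator's closed-form oracle is the squared coherence, so estimator checks
compare against its square root. Self-coherence is identically 1, values are
clipped to [0, 1], and the estimate is invariant to per-channel rescaling.
Degrees of freedom (2 × windows × tapers) are recorded on every estimate.
Jackknife confidence bands are not computed by default: group-level error
bars in this design come from across-animal dispersion, not estimator CIs.

The sample→choice modulation statistic is the fractional change
(choice − sample)/sample, undefined (error) for non-positive sample values.
For T-maze designs, per-epoch coherence is pooled within phase and averaged
across training blocks per animal before group statistics.

## Phase–amplitude coupling

Theta phase and gamma amplitude come from zero-phase FIR band-pass filters
(Hamming-window design, 2 Hz transition width; a symmetric FIR applied by
FFT convolution with exact group-delay compensation) followed by the
analytic signal. The first and last second are trimmed to discard filter and
Hilbert edge transients. Phase 0 is the theta peak; bins are half-open over
(−π, π].

Coupling strength is the Tort modulation index with 18 phase bins:
normalize the phase-binned mean amplitudes to a distribution P, then
MI = (log N − H(P))/log N, the KL divergence from uniform scaled to [0, 1].
Empty bins contribute zero (0·log 0 = 0); an all-zero amplitude series is an
error. The exact coupling algorithm used in any given lab varies, so the
method is deliberately simple and a mean-vector-length alternative
(|⟨A e^{iφ}⟩|/⟨A⟩) is provided. MI is exactly invariant to amplitude scaling
and to phase rotations by whole bins; fewer than 50 theta cycles triggers a
warning. Within-dHipp coupling is the default (channel configurable).

## Behavior

T-maze: rewarded alternation — a choice is correct iff the chosen arm
differs from the sample arm. Performance is the per-10-trial-block fraction
correct, optionally averaged over the last k blocks. Y-maze: arm occupancy
is decided by polygon membership of the tracked position; maximal runs
inside one goal arm lasting ≥ 1 s form bouts (shorter incursions are treated
as tracking jitter). The preference ratio is novel-arm time over total
goal-arm time in the first 60 s of the test phase (full-window ratios
available); zero goal-arm time yields a missing value, never a fabricated 0.
Locomotion is binned path length; speeds are median-filtered over three
samples. Mean per-arm bout speeds feed a paired control test, since a
novel-arm coherence difference should not be a running-speed artifact.

## Statistics

Mixed-design ANOVA (between = group, within = time bin or task phase) is
computed by `pingouin.mixed_anova`; one-way ANOVA F is computed from
explicit sums of squares with Tukey-HSD (statsmodels), LSD (pooled-MSE
pairwise t, unadjusted) or Bonferroni post-hocs. Post-hocs are gated on
omnibus significance at α = 0.05, matching the reporting convention of the
figures this pipeline reproduces; gating can be disabled. Missing cells are
a hard error — animals must be excluded listwise and explicitly, never
silently.

Sphericity: with more than two within levels the Greenhouse–Geisser
correction is available and the default policy is Mauchly-gated ("auto"):
the corrected p is used only when sphericity is rejected. A forced
correction would be grossly conservative in the long-time-course designs
used here (30 bins, 16 subjects), where the epsilon estimate is strongly
biased downward; under the generator's iid within-subject noise the
uncorrected mixed-design F is exact, and the type-I calibration in the
acceptance suite verifies a 5% rejection rate under metric-level nulls.
pingouin reports the corrected p only for the within effect, so the same
epsilon is applied to the interaction's degrees of freedom internally.

Regression of per-animal performance on a coherence metric uses OLS with
group-identity dummies ("all groups" scope; the partial correlation r_p is
recovered exactly from the slope's t statistic, r_p = t/√(t²+df)) or simple
Pearson regression within the wildtype subgroup. Slope uncertainty uses a
stratified (within-group) bootstrap with a normal-approximation interval and
a Student-t critical value at the residual degrees of freedom; percentile
intervals undercover at cohort-sized n (the slope's sampling distribution is
t-shaped, and within-group resampling shrinks the bootstrap SD), and the
calibration checks in the acceptance suite confirm ≥95% coverage for the
t-based interval at nominal 95%. Tests are two-sided throughout; raw p
values are reported and no trend band is encoded.

## The generator

Each channel is a weighted sum of shared narrowband Gaussian sources plus
independent white noise. A source is white noise driven through an order-4
Butterworth band-pass applied forward-backward (so spectral peaks have
realistic width and nonzero peak-frequency variability, unlike sinusoids);
its one-sided PSD at the band center equals the nominal source power. The
model's magnitude-squared coherence has the closed form

    C(f) = (g_a g_b P(f))² / ((g_a² P(f) + N_a)(g_b² P(f) + N_b)),

evaluated with the filter's actual |H(f)|⁴ response; this is the oracle the
coherence estimators are validated against (e.g. P = N at unit gains gives
C = 1/4, magnitude 1/2). PAC is injected as a gamma carrier with amplitude
A₀(1 + d·cos φ_θ), φ_θ the theta source's instantaneous phase, which makes
the modulation index target brute-force computable and monotone in d.

Habituation is an exponentially decaying theta-source envelope
A(t) = A₀e^{−t/τ} (τ = ∞ for the sustained, knockout-like profile), and the
open-field tracking is a bounded correlated random walk whose step rate
scales with the instantaneous theta amplitude — a modeling convenience that
makes habituation jointly visible in the LFP and behavior, not a mechanistic
claim. Y-maze test phases alternate hub transits with goal-arm bouts whose
arm choice is Bernoulli(preference target) and whose durations share one
exponential distribution across arms, so the indifferent null has an exact
expected preference ratio of 0.5; novel-arm bouts can carry a theta
amplitude gain (raising power and coherence together) and a speed gain.
T-maze sessions draw choice correctness Bernoulli(p) and can scale the
shared sources inside choice decision windows to emulate sample→choice
coherence modulation. All randomness descends from one seed through named
substreams (lfp, behavior, outcomes), so outputs are bit-reproducible.

Virtual cohorts draw each animal's theta amplitude from a normal
distribution with CV 0.1 (truncated at 0.2). The standard habituation
cohort (8 decaying-theta vs 8 sustained-theta animals, 5-min sessions at
1 kHz) sets the decay time constant so that the end-of-session group
separation in theta power equals 2× the between-animal power SD — a
moderate, calibrated effect on the analyzed variable, not a dramatic one.

**What the generator does not emulate:** 1/f background structure, movement
and chewing artifacts, volume conduction, electrode drift, state transitions
(sleep/rest), spike leakage, and non-sinusoidal theta waveform asymmetry.
Passing parameter-recovery tests therefore demonstrates estimator
correctness and pipeline integrity under the stated generative model, not
robustness to every artifact of real recordings.

## Problem sizes and numerical choices

Validation workloads are sized for a laptop-class single core: coherence
recovery uses 120-s sessions; PAC exactness 300-s sessions; the
habituation-power property runs 100 simulated experiments of 16 animals ×
300 s through the full LFP → spectrogram → binned-metric → ANOVA pipeline,
with the 1000-run type-I calibration performed on metric-level null cohorts
(the ANOVA's calibration does not depend on how the metrics were produced);
the preference-ratio null averages 1000–2000 simulated test phases. Peak
frequencies report the lowest-frequency maximizer on ties; coherence values
are clipped into [0, 1] against floating-point excursions; degenerate
statistics (zero error variance) are flagged rather than raising.

## Known limitations

Only two channels are modeled (no reference/ventral-hippocampal channels);
no directed connectivity (Granger, phase-slope), imaginary coherence or
cross-regional PAC; no wavelet analyses; the ANOVA layer covers balanced
designs only (unbalanced data must be reduced explicitly); vendor formats
(Open Ephys, NWB) are out of scope for the readers.
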