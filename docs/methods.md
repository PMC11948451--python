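# Methods

This note documents the models and procedures implemented in `neurosrt`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect results.

## Signal model

All analyses operate at 64 Hz on a 1–8 Hz band. The stimulus feature is
the broadband amplitude envelope: Hilbert magnitude → power-law
compression with exponent 0.6 (approximating cochlear compression) →
zero-phase band-pass (order-3 Butterworth high-pass and low-pass, each
applied forward and backward, i.e. an effective 12th-order band-pass) →
polyphase resampling with a Kaiser anti-alias window. The band-pass
removes DC, so envelope values may be negative; models consume the signal
as-is. Audio intended to spectrally match a reference corpus is first
passed once (causally) through a first-order low-pass at 2 kHz.

EEG preprocessing is deterministic: channels whose RMS exceeds 3× the
mean RMS across channels (pooled over trials, detection made once per
recording) are replaced by Perrin-style spherical-spline interpolation
(stiffness 4, 50-term Legendre kernel, 10⁻⁵ diagonal regularization;
cross-checked against MNE's implementation in the tests), then
common-average reference → 1–8 Hz zero-phase band-pass → resample to
64 Hz → division of all channels by the mean per-channel SD (one scalar
per trial, preserving relative topography) → common-average reference
again. Component-based artifact removal is intentionally out of scope; a
hook is provided where users of real recordings can insert it.

## Lagged ridge regression (decoder and encoder)

Both directions share one core: a design matrix with one row per time
sample carrying the signal at every (channel, lag) in the decision
window; out-of-window samples are zero-padded, and trials are never
concatenated across the lag boundary. The backward model predicts the
envelope at time t from EEG at t+τ, τ ∈ [−100, 350] ms (a causal neural
response with an acausal margin); the forward model predicts each channel
from the envelope at t−τ, τ ∈ [−100, 500] ms.

The ridge solution is computed on mean-centered columns as
(XᵀX + λ·m̄·I)w = Xᵀy with m̄ = trace(XᵀX)/(n_rows·n_cols), the mean
per-sample power of the design; the intercept restores the target mean.
This scaling makes λ invariant to the amplitude units of the data while
reproducing, on unit-variance minute-scale trials, the behavior of
common TRF toolboxes in which λ = 100 is a mild penalty and a decade grid
from 10⁻⁴ to 10¹⁰ brackets the useful range. The decoder's λ is selected
per participant by leave-one-trial-out cross-validation on the
clean-speech trials (mean held-out Pearson r; exact ties break toward
the larger λ); the final decoder pools the rows of all clean trials. The
encoder uses λ = 100 fixed across participants and conditions, and its
per-condition TRF is the mean of the leave-one-out fold models.

Numerics: per-trial Gram matrices and cross-products are accumulated
once; each leave-one-out fold is solved for the whole λ grid from a
single eigendecomposition of the fold's centered Gram matrix (tiny
negative eigenvalues from rank-deficient noise-free data are clipped to
zero). Single fits use a Cholesky solve; λ = 0 on a singular Gram matrix
raises an error advising λ > 0.

## SRT estimation

Reconstruction accuracy versus SNR is modeled by a fixed-asymptote
sigmoid, S(SNR) = (p−b)/(1+exp(4s/(p−b)·(m−SNR))) + b, with p the mean
clean-condition accuracy (clean accuracies come from leave-one-out within
the clean condition, so no trial is reconstructed by a decoder trained on
it) and b the noise floor: the mean Pearson correlation between the
reconstructed envelopes of the noise trials and a pool of 68 mismatched
envelopes never presented in those trials, series truncated to the common
length. Only s ∈ [0, 10¹⁰] and m ∈ [−10¹⁰, 10¹⁰] are fitted, by bounded
least squares (analytic Jacobian, tolerances 10⁻¹²) on the trial-level
points of the five noise conditions. s starts at 0; m starts uniformly
within ±10 dB of −2.52 dB, a normative behavioral SRT for the sentence
test emulated here. One hundred restarts are run and the parameters of
the ten restarts with the highest R² are averaged; R² is computed on the
trial-level points (the choice between trial-level and condition-mean R²
was open; trial-level matches the fit's own objective). m is the
SRT_neuro; no bias correction is applied. The whole procedure is repeated
(default 100 times) with fresh restart seeds, and the largest pairwise
difference among the repeated midpoints is reported as the robustness
spread.

Fits are attempted only for participants whose 16 clean-condition
accuracies exceed the noise floor in a one-sided two-sample permutation
test at α = 0.05. The gate compares equal counts, so the within-trial
floor means it uses are computed from the clean-trial reconstructions
against the same mismatch pool (the floor entering b still comes from
the noise trials). Population-level increases of accuracy with SNR are
tested between adjacent conditions with one-sided paired sign-flip
permutation tests on participant means — exact enumeration of all 2ⁿ
sign patterns when n ≤ 14, otherwise 10⁴ random patterns with the
add-one p-value; either way the p resolution is finer than 0.01.

## TRF deflection analysis

The mean TRF over a global selection of 17 electrodes (ranked by
grand-average prediction accuracy across participants and all
conditions, ties broken by montage order) is parameterized per condition
by three Gaussians a(t) = p·exp(−((t−l)/w)²), fitted by bounded least
squares on the samples inside each component's latency window: P1
p∈[0,5], l∈[0,100] ms; N1 p∈[−5,0], l∈[70,150] ms; P2 p∈[0,5],
l∈[100,300] ms; w∈(0,50] ms for all. Fits with R² < 0.5 are excluded;
latency estimates pinned at a window boundary are flagged unreliable.
Only conditions whose per-trial prediction accuracy (mean over the 17
electrodes) significantly exceeds an encoder noise floor (mismatched
envelopes, permutation test at α = 0.05) enter the analysis.

SNR effects on the six features (3 components × latency/amplitude) are
estimated with random-intercept linear mixed models fitted by maximum
likelihood (statsmodels MixedLM; optimizer fallbacks lbfgs → bfgs →
powell → nm, and pooled OLS when the between-participant variance
collapses to zero, where the mixed model degenerates to OLS). The SNR
regressor is in dB relative to the behavioral SRT, the clean condition
excluded. The fixed effect is assessed by a Wald t-test with
df = n_obs − n_groups − 1; this df convention is reported as-is rather
than forced to match any particular software. Holm–Bonferroni controls
the family-wise error over the six tests.

## Behavioral staircase

Five-word sentences are scored by words correct. The noise level changes
by ΔL = (p_previous − p_target)·g with p_target = 0.5, g = 8 dB for
sentences 1–4 and 4 dB for sentences 5–40 (so the SNR changes by −ΔL);
the track starts at −10 dB and runs 40 sentences; SRT_beh is the mean SNR
of sentences 5–40. No rounding is applied to the SNR track.

## Synthetic-data generator

The generator exists so that every stage is testable without any
recording. It emulates the study design: per simulated participant, five
noise conditions at SRT_beh + {−4,−2,0,+2,+4} dB plus clean speech,
16 trials of ~1 min per condition (scaled down where noted), 64 channels
on a standard BioSemi layout.

- **Envelopes** are 1–8 Hz filtered Gaussian noise, mean-removed, unit
  variance — speech-like in modulation spectrum only.
- **TRF kernels** are sums of three Gaussians over lags 0–400 ms whose
  latencies and amplitudes depend linearly on the condition's relative
  SNR. Defaults: P1/N1/P2 baselines (0.4, −0.5, 0.6) a.u. at
  (50, 120, 200) ms, widths (20, 25, 35) ms, latency slopes
  (−0.940, −1.517, −6.001) ms/dB and amplitude slopes
  (0.011, −0.015, 0.018) a.u./dB — latencies shorten and amplitude
  magnitudes grow with SNR. The clean condition maps to a relative SNR
  of +6 dB (highest gain, shortest latencies). A latency-order inversion
  (possible at extreme SNRs under linear extrapolation) raises an error.
- **Topography** is a smooth unit-norm field peaking frontocentrally,
  made zero-mean across channels: an average-referenced potential field
  is zero-mean by construction, and this keeps the topography invariant
  under the pipeline's common-average referencing.
- **Channels** are g(SNR) · topography × (envelope ⊛ kernel) plus
  noise_level × (0.9·1/f + 0.1·white) noise, independent per channel.
  The neural gain g is logistic in absolute SNR, centered at the
  listener's true SRT with slope 0.5/dB, so the decoder's
  accuracy-versus-SNR curve is sigmoid with its informative region at
  the behavioral threshold — the structural assumption the SRT_neuro
  method relies on. The paper-level literature gives no quantitative
  SNR→gain link; this is the generator's modeling choice.
- **noise_level = 6.0** was fixed by a forward-model design experiment
  before any end-to-end testing: it yields clean-condition
  reconstruction accuracies near 0.5 at study scale with trial-level
  scatter comparable to published envelope-tracking data, and midpoint
  biases below ~0.5 dB across plausible gain slopes.
- **Listeners** answer sentences via Binomial(5, σ(0.5·(SNR−SRT_true))),
  so the per-word probability is exactly 0.5 at the true SRT.
- **Seeding**: one master generator per dataset draws a sub-seed per
  envelope and per trial, in a fixed order; every trial records its
  sub-seed. Equal (config, seed) runs are byte-identical.

What the generator does **not** emulate: real speech envelopes (syllabic
rhythm, pauses), eye/heart/line artifacts (the artifact-removal stage is
out of scope), electrode-position noise, inter-channel noise
correlations, and any nonlinearity between stimulus SNR and neural gain
beyond the logistic assumption. Passing tests therefore demonstrate that
the estimation machinery recovers the quantities this statistical
structure defines, not that it would achieve any particular accuracy on
real recordings.

## Problem sizes used in validation

The end-to-end cohort check runs 20 listeners at 8 trials × 30 s per
condition with 10 robustness repetitions — the package's scaled-down
standard validation configuration; at these sizes the median
|SRT_neuro − SRT_true| is ~0.2 dB and all listeners land within 2 dB.
Permutation-test calibration uses 1000 null replicates on the tests' own
null model (exchangeable Gaussian samples). The noise-free TRF recovery
fixture uses 8 trials × 60 s: ridge shrinkage bias scales as λ/n, and a
fixed λ = 100 needs minute-scale pooled folds for kernel correlations
above 0.99.

## Known limitations

- With the −100…350 ms decision window, even noise-free EEG generated by
  a 0–400 ms kernel cannot be decoded perfectly: the optimal inverse
  filter needs more support than the window allows (measured ceiling
  r ≈ 0.989; r ≈ 0.997 with a −100…500 ms window). This is a property of
  the window/kernel pair, not of the solver.
- Peak-level latencies and amplitudes of overlapping components are not
  separately identifiable: with N1 and P2 overlapping in time, their
  fitted per-dB latency slopes blend (their sum is conserved), and an
  SNR-dependent gain confounds amplitude slopes entirely. The TRF
  recovery validation therefore holds the gain constant, checks the
  isolated P1 against its generating slopes, and checks the N1+P2 sum —
  the same caution applies to interpreting deflection statistics on real
  data.
- TRF amplitudes are in arbitrary units after SD normalization;
  amplitude effects should be interpreted relatively (the validation
  rescales by the fitted intercept).
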