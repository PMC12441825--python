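# Methods

This note documents the models implemented in `expectdecode`, the choices
made where the design was genuinely open, and what the synthetic-data
closed loops do and do not establish.

## Trial design

The schedule crosses visual expectancy (cue orientation matches the target)
with motor expectancy (target appears immediately on button release), each
at 75% validity, giving cell probabilities 9/16, 3/16, 3/16, 1/16. Counts
are balanced **exactly at the experiment level**: per-block exact counts are
impossible at 72 trials/block (72·9/16 = 40.5), so the label sequence is
drawn with exact totals and pseudo-randomly interleaved across the session.
A 720-trial session therefore holds 405/135/135/45 trials per cell.

Valid cues equal their target exactly (no jitter is modeled); invalid cues
sit at a circular orientation distance drawn uniformly from (30°, 90°] on a
random side. The visual-to-motor-cue delay is uniform on [250, 1500] ms;
motor-unexpected trials add an extra target delay uniform on
(0, width/3] = (0, 416.7] ms, strictly positive so a violation always
involves a real delay.

`match_trials` equates cell counts at the smallest cell (45 for the default
session) by retaining, within each over-represented cell, the trials with
the shortest visual-to-motor delays (ties broken by trial index, original
order preserved; idempotent). Note what this does and does not achieve:
counts are equated exactly, but because the smallest cell keeps its full
delay spread while subsampled cells keep only their shortest-delay third
(or ninth), the retained delay *distributions* are compressed in the
subsampled cells. No retention rule based on the visual-to-motor delay can
simultaneously equate counts against the smallest cell and match its delay
distribution.

## Synthetic EEG and the decoding closed loop

Epochs are generated by running the forward model in reverse:
`data(t) = s · W_true · c(θ) · profile(t) + noise`, with `W_true` a
smoothed random sensor-weight matrix (any full-rank weight matrix suffices
for recovery testing), `c(θ)` the five-channel basis response, `profile(t)`
a raised-cosine gain over the signal window (default 50–300 ms), and noise
drawn with exponentially decaying inter-sensor correlation
`corr(i,j) = exp(−|i−j|/3)` — the high neighboring-sensor correlation
regime that motivates covariance-aware spatial filters. `snr` is the ratio
of signal RMS (inside the signal window) to noise RMS; the default of 1 is
a realistic single-trial EEG regime, and 0 gives pure noise for null
calibration. All generators are pure functions of their arguments and seed.

The decoder estimates forward weights per channel by one-regressor least
squares exactly as the model is written (not a joint multichannel
regression), estimates each channel's residual covariance with divisor
n−1, shrinks it toward the scaled identity `ν I` (ν = mean diagonal) with
the analytic Ledoit–Wolf intensity, and forms unit-gain spatial filters.
If training residuals vanish (noiseless data), the covariance has no scale
and the filter falls back to the identity-covariance case, flagged as
degenerate. Cross-validation is 10-fold over trials, independently per
timepoint, with no temporal smoothing; training pools all condition cells
of the (matched) schedule and accuracy is reported overall and per cell.

**Intrinsic decoding bias.** The basis
`f(θ−φ) = max(0, cos(π(θ−φ)/90))⁴` is half-wave rectified on the
doubled-angle circle and is therefore not band-limited: its 4th
doubled-angle harmonic (Fourier coefficient 1/16) aliases onto the first
harmonic under 5-channel sampling. The phasor estimate `θ̂ = arg(z)/2`
consequently carries a deterministic, 36°-periodic, zero-mean bias of up to
≈ 5.3°, independent of SNR. High-SNR closed loops therefore reach accuracy
r ≈ 0.99 with per-trial errors up to ≈ 7°, and per-trial recovery cannot be
driven below the aliasing envelope with this basis and decoder. Decoding is
exactly equivariant under orientation shifts that are multiples of the 36°
channel spacing (the bias function is 36°-periodic); it is not equivariant
under arbitrary shifts.

Accuracy doubles the decoded-minus-presented differences before projecting
onto the zero-error direction, consistent with the doubled-angle mapping of
the decoder; `double_angle=False` selects the raw-difference variant.
A phasor of negligible magnitude (relative tolerance 1e−12, e.g. the exact
cancellation of all-equal channel responses) decodes to NaN — undefined,
not an error — and is excluded from accuracy with its count reported.

## Behavioral mixture model

Errors `e = response − target` are wrapped to (−90°, 90°] and doubled, so
the mixture `p(e) = (1−g)·vM(2e; 0, κ) + g/(2π)` has a proper uniform
component of density 1/(2π); κ is reported in doubled-angle units. The
likelihood is maximized by L-BFGS-B from a 5×5 grid of starts over (κ, g),
bounded at κ ≤ 200 (stability of the Bessel ratio; hitting the bound sets a
flag). Ties resolve to the highest log-likelihood, then the lowest κ. The
circular standard deviation is `σ = ½·√(−2 ln R₂)·180/π` with R₂ the mean
resultant of the doubled errors; R₂ < 0.05 (σ beyond ~60°) triggers a
large-dispersion warning because σ is then effectively unbounded.

One identifiability caveat: at κ → 0 the von Mises component is itself
uniform, so on truly uniform data the likelihood is flat along a ridge
between (g → 1, any κ) and (κ → 0, any g); the identifiable quantity is the
implied mean resultant length (1−g)·A₁(κ), not g alone.

## ANOVA, Bayes factors, and cluster statistics

Each effect of the 2×2 within-subject design has one degree of freedom, so
its F equals the squared one-sample t of the per-subject contrast
(difference of marginal means for main effects); this identity is used
throughout and makes the permutation machinery a handful of vectorized
einsums. Partial η² is `F·df₁/(F·df₁ + df₂)`. Bayes factors use the JZS
construction (Cauchy prior on standardized effect size, scale √2/2),
evaluated by adaptive quadrature over the inverse-gamma mixing variable
and applied to each effect's subject-level contrast; the zero-variance
degenerate cases return +inf (nonzero mean) or NaN (all-zero differences).

Cluster correction: per-timepoint F values are thresholded at the
cluster-forming alpha (.05); maximal runs of adjacent suprathreshold
timepoints form clusters with mass = sum of F. Each permutation shuffles
the four cell labels within every subject — one shuffle reused across
timepoints, preserving temporal autocorrelation — and contributes its
maximum cluster mass (0 if none) to the null. A cluster is significant if
its mass exceeds the null's 95th percentile; corrected p-values use the
(1+k)/(1+N) estimator so they are never zero. All three effects share the
omnibus label shuffle; restricted interaction schemes are out of scope. A
one-sample variant (sign-flipping whole subject time courses, statistic t²)
serves the accuracy-versus-chance test.

Calibration at the implemented scale (20 subjects, 180 timepoints, 1,000
permutations): the measured familywise error rate per effect in a
2,500-experiment global-null run is 0.050–0.052, i.e. the procedure is
essentially exact; single-effect estimates from 500-experiment batches
scatter around that with a binomial standard error of ≈ 0.01.

## Time-resolved LDA

Features are all sensor amplitudes at one timepoint. The classifier is
binary LDA, `w = Σ_pooled⁻¹(μ₁−μ₀)` with the analytic shrinkage intensity
on the pooled covariance and the threshold at the midpoint of projected
class means. Because the design is 75/25 imbalanced, the majority class is
randomly subsampled to the minority count (fresh per repeat, default 2
repeats) before stratified 10-fold cross-validation; accuracy is averaged
over folds and repeats. This makes 50% the true chance level; the null
calibration at 720 trials recovers 50% within a fraction of a point. (At
much smaller trial counts cross-validated accuracy at chance is biased
slightly below 0.5 — the usual small-sample CV pessimism — which is why
calibration checks use hundreds of trials.)

## Pupillometry

Preprocessing applies, in this fixed order: (1) blink samples extended by a
100 ms buffer on each side are marked missing; (2) samples with
|x − median|/MAD > 2.5 are marked missing; (3) linear interpolation over
missing runs; (4) zero-phase first-order Butterworth filtering; (5)
z-scoring of the continuous trace; (6) epoching to [−500, 1500] ms around
target onset; (7) down-sampling to 125 Hz (250 samples per epoch). Epochs
leaving the recording, or with missing fraction at or above the configured
limit, are excluded with a logged reason. The default passband (15.6–500 Hz)
reproduces the protocol as printed but would remove essentially all pupil
dynamics (< 4 Hz) and its upper edge equals Nyquist at 1000 Hz; the
pipeline warns loudly on these defaults, drops any cutoff at or above
Nyquist, and all closed-loop analyses here use a 4 Hz low-pass profile. No
baseline correction is applied inside the pipeline.

The generator composes a hippus-like bounded slow oscillation
(0.08–0.15 Hz sinusoid; bounded at √2 SD so an honest baseline never
trips the 2.5-MAD outlier fence), small white measurement noise, per-trial
dilations (gamma-family kernel peaking at 930 ms, scaled to unit mean over
the 1.5 s post-onset window so per-cell amplitudes are in post-onset-mean
z-units), Poisson blinks as disjoint missing segments, and rare large
spikes. Because the background is slow, its variance survives the 4 Hz
low-pass and the z-scoring step approximately preserves the generator's
amplitude units; recovery checks use baseline-corrected (post-minus-pre)
epoch means, which remove the shared slow background per trial.

## What the synthetic loops do and do not show

The generators deliberately share their structural assumptions with the
analyses (linear forward model, von Mises errors, stationary Gaussian
sensor noise, additive pupil dilations). Passing closed loops therefore
demonstrates internal consistency, correct implementation of each formula,
and honest calibration of the null procedures — not robustness to the
nonstationarities, artifacts, 1/f spectra, eye movements, or model
misspecification of real recordings. Real-data ingest (BrainVision/EDF via
MNE, EyeLink ASC subset) is provided but assumes externally cleaned input:
ICA artifact rejection and bad-channel interpolation are upstream
responsibilities.

## Numerical choices and limitations

- Epoch lengths are always computed as `round(window · rate)`; the default
  EEG grid is 179 samples (256 Hz over [−200, 500] ms).
- The analytic shrinkage intensity is clipped to [0, 1]; a zero-scale
  covariance falls back to the identity with a degeneracy flag.
- Permutation p-values are never zero by construction; significance uses a
  strict inequality against the 95th percentile.
- Problem sizes in the validation suite (e.g. 500 null experiments × 1,000
  permutations; 20 null LDA datasets) were chosen to put Monte Carlo error
  comfortably inside each tolerance on a single core.
- The schedule generator draws orientations i.i.d. uniform; it does not
  stratify orientations across cells, model inter-trial intervals,
  response-phase timing, or practice blocks.
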