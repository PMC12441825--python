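# expectdecode

Analysis pipeline for probabilistic-cueing experiments that ask whether
*expectation* changes how the brain represents a stimulus. It covers the
full chain used in cross-domain (visual × motor) expectancy studies with
EEG, continuous orientation reproduction, and pupillometry:

- **Trial design** — a counterbalanced 2×2 schedule in which a visual cue
  predicts the target orientation with 75% validity and a motor cue predicts
  immediate target onset with 75% validity, plus the confound-matched
  subsampling that equates trial counts across the four cells.
- **Inverted encoding model (IEM)** — orientation decoding from
  multichannel epochs via a five-channel tuning basis
  `f_k(θ) = max(0, cos(π(θ−φ_k)/90))⁴`, per-channel least-squares forward
  weights `W` (so sensor data follow `B = WC + E`), noise covariance from
  training residuals with analytic (Ledoit–Wolf) shrinkage, and spatial
  filters `v_i = Σ̃_i⁻¹w_i / (w_iᵀΣ̃_i⁻¹w_i)` that satisfy `v_iᵀw_i = 1`.
  Decoding uses the population phasor `z = Σ_k c_k e^{2iφ_k}`,
  `θ̂ = arg(z)/2`, and accuracy `r̂ = Re[(1/n) Σ_j e^{i·2(θ̂_j−θ_j)}]`.
- **Behavioral mixture model** — reproduction errors as a von Mises +
  uniform mixture on the doubled-angle circle, separating precision (κ)
  from guess rate (g), fit by multi-start maximum likelihood.
- **Statistics** — 2×2 repeated-measures ANOVA with partial η², JZS paired
  Bayes factors (Cauchy scale √2/2), and cluster-mass permutation
  correction for time-resolved data (within-subject label shuffles,
  max-cluster-mass null, 95th-percentile significance).
- **Time-resolved LDA** — shrinkage LDA classification of trial expectancy
  per timepoint, with majority-class subsampling so that 50% is the true
  chance level, and a sign-flipping cluster test against chance.
- **Pupillometry preprocessing** — blink removal (100 ms buffer), MAD
  outlier removal, interpolation, zero-phase Butterworth filtering,
  z-scoring, epoching to [−500, 1500] ms, down-sampling to 125 Hz.
- **Synthetic data** — generators for EEG epochs (forward model run in
  reverse plus spatially correlated noise), mixture-model behavior, and
  pupil traces with known ground truth, so every stage can be validated in
  closed loop.

The package is aimed at cognitive-neuroscience researchers who want a
tested, deterministic re-implementation of this analysis chain — either to
analyze their own epoched data or to run design/power simulations before
collecting any.

## Worked example

```python
import numpy as np
import expectdecode as ed

# 720-trial session: 10 blocks x 72 trials, 75%/75% cue validity
schedule = ed.generate_schedule(n_blocks=10, trials_per_block=72, seed=1)
matched = ed.match_trials(schedule)
print(len(schedule), "trials ->", len(matched), "after matching")

# synthetic EEG with orientation-tuned signal, then decode it back
dataset = ed.simulate_eeg(schedule, ed.TuningConfig(n_sensors=64, snr=2.0), seed=1)
result = ed.crossvalidated_decode(dataset, k=10, seed=0)
peak = result.accuracy["all"].max()
print(f"peak decoding accuracy r = {peak:.3f}")

# behavioral mixture model on simulated reproduction responses
responses = ed.simulate_behavior(schedule, seed=2)
errors = ed.response_error(responses, schedule["target_orientation_deg"].to_numpy())
fit = ed.fit_mixture(errors)
print(f"kappa = {fit.kappa:.2f}, guess rate = {fit.guess_rate:.3f}")
```

Output:

```
720 trials -> 180 after matching
peak decoding accuracy r = 0.988
kappa = 7.86, guess rate = 0.273
```

720 trials shrink to 45 per cell (180 total) because the smallest design
cell (double violation, 6.25%) holds 45 trials. The decoding accuracy `r`
is 1 for perfect decoding and 0 at chance; at SNR 2 the decoder recovers
the orientation almost perfectly at the peak of the signal window. The
mixture fit recovers the generator's ground truth (κ = 8, g = 0.25) within
sampling error.

A thin CLI mirrors the library: `expectdecode simulate schedule|eeg|behavior|pupil`,
`expectdecode decode|behavior|cluster|lda|pupil` (see `--help`).

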