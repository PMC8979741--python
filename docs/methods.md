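# Methods

This note records the models, conventions and numerical choices behind
`eegaug`, in the order the pipeline runs.

## Synthetic EEG generator (`eegaug.simulate`)

**What it emulates.** The generator reproduces the DEAP recording
geometry — `n_participants × n_trials` trials of `n_channels × duration·fs`
samples (32 × 40 × 32 × 8064 at 128 Hz by default, 63 s per trial of which
the first 3 s are a pre-stimulus baseline) — together with continuous 0–9
self-assessment ratings in the DEAP column order (valence, arousal,
dominance, liking).

**Signal model.** Each trial is a sum of independent band-limited Gaussian
components plus broadband noise:

```
x_c(t) = Σ_b a_{b,c} · s_{b,c}(t) + σ · w_c(t)
```

where `s_{b,c}` is unit-variance noise confined to band `b` and the
amplitudes encode a latent emotion state (arousal `a`, valence `v`, both
Uniform(0,1) per trial):

* `a_{b,c} = base_b · (1 + c_b · (2a − 1))` — the arousal coupling `c_b`
  scales β and γ up and α down (defaults: θ (1.0, 0), α (1.5, −0.5),
  β (0.8, +0.8), γ (0.5, +0.6));
* on the 14 homologous electrode pairs the α amplitude is additionally
  tilted right-vs-left by valence: right × (1 + r/2), left × (1 − r/2)
  with `r = asym_effect · (2v − 1)` (default `asym_effect` = 0.4).

Ratings are `clip(9·level + N(0, rating_noise_sd), 0, 9)` with
`rating_noise_sd` = 0.5 by default; dominance and liking come from
independent latents and are never classified.  These couplings are a
simulator convention chosen so that all three feature families carry a
recoverable signal — they are not a neurophysiological claim, and passing
tests on this data demonstrates pipeline correctness, not performance on
real EEG.  Real data differ in ways the simulator deliberately omits:
1/f background spectra, artifacts (blinks, EMG), inter-participant
variability and nonstationarity.

**Band-limited synthesis.** Band components are defined by zero-phase
(forward–backward) 4th-order Butterworth band-pass filtering of white
noise.  Numerically this is done in the frequency domain: the rFFT of
filtered white noise is complex Gaussian with per-bin standard deviation
proportional to the filter's squared magnitude response |H(f)|², so the
component is drawn directly on the bins where the response is
non-negligible (> 1e-8 of peak) and all bands share one inverse FFT — the
circular-boundary equivalent of `filtfilt`, several times faster.  The
Butterworth design edges are inset by 10 % of the bandwidth so that ≥ 99 %
of each component's theoretical power lies inside the nominal band; the
spectral-fidelity test (≥ 95 % of Welch power in band) then holds with
margin even for the 2-Hz-wide slow-α band.  Draws are float32 — synthetic
EEG has no use for 52-bit mantissas — and every draw comes from one seeded
`numpy` Generator, so datasets are bit-reproducible.

**Strong-coupling preset.** `SynthConfig.strong_coupling()` (α coupling
−0.7, β/γ +0.9, `asym_effect` 1.0, `noise_sd` 0.1, noiseless ratings) is
the planted-signal condition used by recovery tests: the latent state is
then essentially deterministic given the features, so a linear classifier
should recover the binarised labels with high accuracy.

## Feature extraction (`eegaug.features`)

* **Analysis segment**: the final 60 s (7680 samples) of each trial; the
  3-s baseline is discarded.  Configurable via `segment_s`.
* **PSD estimator**: Welch, 1-s Hann windows, 50 % overlap, no detrend.
  1 Hz resolution guarantees ≥ 2 bins in the narrowest band.  The PSD
  integral approximates signal variance (Parseval); unit tests pin this to
  closed forms (sinusoid A²/2 within 5 %, white-noise variance within 10 %).
* **Band average**: arithmetic mean of the density over bins with
  `f_lo ≤ f < f_hi` (half-open, so adjacent bands never share a bin).  No
  log transform by default; `log10=True` is available.
* **Asymmetry**: right-channel minus left-channel band average, 14 pairs ×
  (θ, α, β, γ).  Swapping the members of every pair negates all 56 values.
* **Time domain**: per channel (mean, variance, zero-crossing count,
  mean absolute first difference) = 128 features.  The 344-feature layout
  reserves 128 time-domain slots but the classic trio (mean, variance,
  zero crossings) fills only 96; the fourth statistic is this package's
  convention to fill the layout, and
  `statistics=("mean", "variance", "zcr")` gives the 96-feature variant.
* **Zero crossings**: positive↔negative transitions only; exact zeros are
  transparent (the crossing is decided by the nearest non-zero neighbours),
  so `[1, 0, −1]` counts one crossing.
* **Scaling**: per-column min–max onto [−1, 1], fitted on training rows
  only; constant columns map to 0 and invert back to their constant.

Column layout is `[160 PSD | 56 asymmetry | 128 time-domain]`,
channel-major/band-minor, with deterministic names
(`psd_Fp1_theta`, `asym_Fp2_Fp1_alpha`, `td_Oz_variance`, …).

## Conditional WGAN (`eegaug.gan`)

Generator `(z ∈ R¹⁰⁰, one-hot y) → R^d` with hidden widths (256, 512),
ReLU, tanh output (bounded to the normalised feature space); critic
`(x, one-hot y) → R` with hidden widths (512, 256), ReLU, linear head.
Training: 500 generator steps, 5 critic updates per generator update,
batch 32, Adam(lr 2e-4, β = (0.5, 0.9)), gradient penalty λ = 10 on
`x̂ = ε·x_real + (1−ε)·x_fake` (gradient taken w.r.t. the feature part;
the label stays fixed).  An `epochs` alias converts to
`epochs · ⌈n/batch⌉` steps for users who think in passes over the data;
the step budget is the canonical setting.

The networks run on the package's NumPy MLP core (`eegaug._mlp`).  For a
ReLU critic the gradient penalty admits an exact double-backprop in closed
form — second derivatives of ReLU vanish almost everywhere, so with
backward signals `s_l = ∂D/∂z_l` and a tangent pass
`q_l = (q_{l-1} W_l) ⊙ m_l` seeded by `q_0 = ∂P/∂g`, the penalty's weight
gradient is `∂P/∂W_l = q_{l-1}ᵀ s_l` and bias gradients vanish.  This is
verified against finite differences in the unit tests.  Training,
sampling and gating are bit-reproducible under fixed seeds on one
platform.

**Quality gate.** The visual real-vs-generated distribution check (PCA
scatter of the two leading components Z1/Z2) is operationalised as a
two-sample test: squared MMD with an RBF kernel (bandwidth = median
pairwise distance of the real sample; biased V-statistic, hence ≥ 0)
computed on the full feature vectors.  The pass threshold is the 95th
percentile of MMD² between 200 seeded random half-splits of the real data
— an empirical null for "same distribution" at this sample size.  Real
rows are put in lexicographic order before bandwidth estimation and
resampling so the gate is invariant to row order.  Gating is whole-batch:
either all requested fake rows are appended (de-normalised through the
training scaler, labels in proportion to the training labels) or none.

## Classifiers and experiment (`eegaug.classify`, `eegaug.experiment`)

* **SVM**: scikit-learn SVC, linear kernel, C = 1.0, no grid search.
* **DNN**: input → 512 → 256 → 128 → dropout(0.5) → 1 sigmoid, ReLU
  hidden, binary cross-entropy, Adam(lr 1e-3), batch 32, 100 epochs by
  default; dropout is inverted and training-only, so inference is
  deterministic.  The dense parameter count for 344 inputs is
  344·512+512 + 512·256+256 + 256·128+128 + 128+1 = 340,993.
* **Experiment protocol**: "mean ± std" accuracy cells require a source
  of variation, and the only one consistent with a non-zero std for a
  deterministic SVM is repeated re-drawn splits, so each repeat re-draws
  the 90/10 split (1152/128 at DEAP scale), refits the scaler and the
  per-target CWGAN on the training rows, gates and appends each
  augmentation size ({0, n_train, 5000} by default), trains each
  classifier and scores the held-out rows.  Std is the population std over
  repeats (a single repeat reports 0).  Per-cell seeds are derived by
  hashing (base seed, stage, repeat, target, size, classifier), which makes
  cells independent: size-0 cells are bit-identical to a run with the
  augmentation stage disabled, and reruns are bit-identical end to end.
  Test rows are never augmented, never seen by the GAN and never used to
  fit the scaler; a structural test corrupts the held-out rows and checks
  the gate statistics are unchanged.

## Problem sizes in tests and the acceptance script

Defaults keep the full study conditions (32 participants, 1280 trials,
500 GAN steps, 10 repeats, sizes {0, n_train, 5000}).  To keep desk-scale
runs in minutes, the automated checks use scaled instances chosen as the
package's own trade-off between statistical resolution and runtime:

* geometry checks stream the full 32-participant dataset but store only
  counts;
* planted-signal recovery: 12 strong-coupling participants (480 trials),
  10 repeated splits;
* toy CWGAN sanity: the 500-point two-Gaussian problem at the full
  500-step budget;
* the scripted augmentation experiment: 8 participants (320 trials),
  2 repeats, sizes {0, 1×}, full 500-step CWGANs, DNN epochs 30;
* determinism checks: 4 participants, 40-step CWGANs.

## Known limitations

* The simulator's stationary, artifact-free signals make classification
  easier than on real EEG; absolute accuracies here say nothing about
  performance on DEAP recordings.
* The gate calibrates its null from half-splits of the training features;
  with very small n the threshold is noisy and the gate conservative.
* One CWGAN is trained per classification target (arousal-conditioned and
  valence-conditioned separately); a joint 4-way conditioning is out of
  scope.
* The NumPy networks are CPU-oriented; the default full-size experiment
  (10 repeats × 2 targets × 500-step GANs plus DNN fits) runs in hours,
  not minutes.
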