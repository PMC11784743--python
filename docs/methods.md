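# Methods

## Problem setting

Per-user calibration is the main practical cost of EEG-based emotion
recognition. `hatl` asks how much of that cost can be moved onto cheaper
non-EEG sensors: if feature vectors from eye movements, peripheral
physiology or head tracking carry information about a subject's concurrent
EEG band features, a conditional generative model trained on previously
recorded subjects can synthesize the EEG portion of a new subject's
calibration data. Everything in the package operates at the *feature* level
— one row per analysis window — not on raw waveforms.

## Feature extraction

EEG windows are reduced to one value per (channel, band). For profiles
modelled on laboratory EEG caps the feature is differential entropy: the
window is band-passed with a 4th-order zero-phase Butterworth filter and
DE = ½·ln(2πeσ²) is taken on the filtered sample variance σ² (the Gaussian
closed form; a zero-variance window yields −inf and is flagged rather than
silently imputed). For the VR headset profile the feature is average band
power from Welch's periodogram (Hann window, 50 % segment overlap, segment
length min(256, window), 4× zero-padded FFT) integrated over the band with
Simpson's rule. Zero-padding matters: Simpson integration of a near-delta
spectral peak on the raw Welch grid is sensitive to the parity of the peak's
bin index; the refined grid removes that artefact while leaving broadband
spectra unchanged.

Peripheral channels are summarised by eight statistics per window — mean,
standard deviation, min, max, mean |first difference|, mean |second
difference|, total periodogram power excluding DC, and mean signed
central-difference gradient. Using absolute first/second differences and a
signed gradient keeps the three derivative-like features non-redundant.
Head tracking is summarised by min/max/mean/median/std of the frame-to-frame
changes in yaw, pitch and roll (15 values). Windowing uses
L = round(length·fs) samples with hop L − round(overlap·fs); trailing
partial windows are dropped.

Valence/arousal ratings are quadrantised by comparing each axis to the
sample median of the vector passed in; ties map to Low, so the split is
binary and deterministic. Min–max scaling maps each column to [0, 1];
constant columns map to 0; a scaler state fitted on training data is reused
(with clipping) on test and generated data.

## Adversarial architecture and training

The generator input is the concatenation [z, s, one-hot y] with noise
dimension z = 32. Each residual block applies linear → batch norm → ReLU
and concatenates its output to its input, so block k's input width is
in_dim + Σ units[<k]; a final linear layer maps the accumulated width to
the EEG dimension. The output head is linear during training and clipped to
[0, 1] only at synthesis time, matching the min–max-scaled targets without
saturating training gradients. The critic applies
linear → LeakyReLU(0.2) → dropout(0.5) per layer and ends in a scalar;
a sigmoid is applied only for the CGAN variant. Block widths per profile:
generator (64, 128, 256) / critic (128, 64) for the 310-dim profile,
(128, 128) / (64, 64) for the 128-dim profile, (64, 64) / (32, 32) for the
35-dim VR profile, and (32, 32) / (32, 32) for the reduced test profile.

Losses: CGAN uses the saturating cross-entropy pair, computed in softplus
form on logits for numerical stability (mathematically identical to
−E[log D(x,y)] − E[log(1 − D(G,y))]). The Wasserstein variants use
d_loss = E[D(fake)] − E[D(real)], g_loss = −E[D(fake)]; CWGAN clips critic
weights to ±0.01 after every critic step; CWGAN-GP adds
λ·E[(‖∇_x̂D(x̂,y)‖₂ − 1)²], λ = 10, with x̂ = ε·x_real + (1−ε)·x_fake and
ε ~ U(0, 1) per sample. The penalty's forward pass runs the critic without
dropout so the penalised gradient field is well defined; the gradient norm
carries a 10⁻¹² floor inside the square root to keep the second derivative
finite at the origin.

Optimisation is Adam with the shared hyperparameters lr = 2·10⁻⁴,
betas (0.5, 0.9), weight decay 10⁻⁶ (applied to both networks), batch size
64, for 100 epochs — distances plateau well before that cap. The schedule
is the reference Wasserstein schedule: each iteration takes n_critic critic
steps on freshly sampled batches followed by one generator step
(n_critic = 5 for the Wasserstein variants, 1 for CGAN); an epoch is one
generator pass, i.e. ⌊train rows / batch⌋ iterations. Batch norm uses batch
statistics in training and running statistics (momentum 0.1) at inference.
All randomness — initialisation, batch sampling, noise, dropout masks,
interpolation ε — derives from a single integer seed, so training is exactly
reproducible.

Because no deep-learning framework is a dependency, the networks run on a
small reverse-mode autodiff engine included in the package. Its backward
rules are themselves traced operations, which makes gradients first-class
graph nodes and gives the double backpropagation that differentiating the
gradient-penalty term with respect to the critic weights requires. Engine
gradients are tested against central finite differences at both orders.

A fixed held-out batch (20 % of training rows, at most 512) is excluded
from the updates; after every epoch the model records the critic/generator
losses plus the mean row-wise Euclidean distance and the mean per-feature
1-D Wasserstein distance between that batch and generated counterparts.

## Fidelity metrics

Row-wise Euclidean distances pair rows by (label, within-label order).
The 1-D Wasserstein distance is the empirical earth-mover distance (equal
sample sizes: mean |sorted a − sorted b|). KL divergence is estimated from
shared-range histograms (50 bins over the pooled min–max, additive
smoothing 10⁻¹⁰, renormalised), direction KL(real ‖ generated), natural
log; a degenerate pooled range returns 0. Significance uses Welch's
two-sided two-sample t-test; p ≥ 0.05 is reported as "not significantly
different", the desired outcome for generated data. Per-band statistics pool
all channels of a band into one sample per source. Aggregation: Euclidean
mean ± std over row pairs, Wasserstein mean ± std over feature columns. No
multiple-testing correction is applied across bands; the raw p-values are
reported. The per-band comparison is evaluated on the model's held-out batch
— generated data conditioned on an *unseen subject's* non-EEG rows would
additionally carry that subject's unpredictable baseline offset, which is a
property of subject transfer, not of generator quality.

## Recognition benchmark

The ensemble is an RBF-kernel SVM (C = 1.0, gamma = 'scale'), a 100-tree
random forest (Gini, unlimited depth) and an MLP with one 100-unit ReLU
hidden layer (Adam, lr 10⁻³, at most 200 iterations; non-convergence within
the fixed budget is tolerated by design). Metrics come from one-vs-rest
confusion counts: accuracy = ΣTP/n, precision and recall macro-averaged
with empty-denominator classes contributing 0. ROC curves are one-vs-rest,
evaluated as empirical step functions on a common 101-point FPR grid,
macro-averaged, with trapezoidal AUC; per-class scores are predicted
probabilities where available and min–max-mapped decision values otherwise.
Reporting the mean over the three classifiers avoids crediting any single
model's idiosyncrasies.

In the LOSO harness each subject is held out in turn; the GAN trains on all
other subjects (scalers fitted there). The held-out subject's rows are split
chronologically into a calibration portion and a testing portion (profiles:
sessions 1–2 vs 3 when a session vector is present, otherwise ⅔/⅓; an even
½/½; or 80 %/20 %). Five conditions are supported: non-EEG only, one per
GAN variant (classifiers train on synthetic EEG fused with calibration
non-EEG), and real-EEG fusion. In the generated conditions the classifier's
EEG block lives in the GAN's training scale, and the subject's real test
EEG is mapped into that same scale for evaluation. Testing always uses the
subject's real recordings. Fold seeds are global seed + fold index. The
calibration sweep trains on the chronological *prefix* (fraction f) of the
calibration portion — calibration time is the quantity being saved, so the
prefix is the honest subsample — and tests on the remainder of that portion;
the fold's GAN is trained once and reused across fractions. CIS is reported
as the exact value of (1 − B/A)·100.

## Synthetic data

The simulator is a linear-Gaussian latent-factor model chosen for
analyzability: a class-conditional latent u ~ N(μ_class, I) (class means
2.0 apart in latent space) drives both modalities through fixed mixing
matrices; EEG mixes the shared latent with an independent latent in
proportion coupling : (1 − coupling); sensor noise is sd 0.1 for EEG and
0.3 for non-EEG (the weaker modality in emotion datasets); per-subject
effects are additive offsets projected from one shared 2-dimensional
subject state (sd 0.4) into both feature spaces — coherent cross-modal
baselines are what permit a cross-modal generator to compensate subject
drift at all. Coupling is verifiable by regression: predicting EEG from
non-EEG achieves out-of-sample R² ≤ 0.05 at coupling 0 and ≥ 0.5 at
coupling 0.9 with low noise. An optional elementwise tanh provides a
nonlinearity hook (off by default). Defaults: 3 subjects × 400 rows on the
reduced 8 + 4-dim profile — a deliberately scaled-down stand-in for
windowed recordings, where a single 60-s trial already yields ~58
overlapping windows. Class labels are balanced within subject (counts
differ by ≤ 1) and the same seed reproduces the dataset bit for bit.

What passing tests on this simulator do show: the three variants train
stably under the stated hyperparameters; the gradient-penalty variant
tracks the real feature distribution most closely; synthetic-EEG
calibration recovers accuracy between the non-EEG-only and real-EEG
conditions; higher cross-modal coupling yields better synthesis. What they
do not show: performance on real EEG with non-Gaussian, non-stationary
structure, electrode artefacts, or label noise — the simulator has none of
these.

## Numerical and design notes

- Ties at the quadrant median go to Low; medians are computed over the
  vector passed in (per-call scope).
- Constant feature columns scale to 0 and inverse-scale to their minimum.
- Labels are stored as integer indices with a canonical per-scheme class
  order and serialized as names.
- Missing values are rejected by validation, never imputed.
- The t-test returns (0, 1) for identical constant samples, where the Welch
  statistic is undefined but the scientific answer ("no difference") is not.
- Checkpoints are single-file numpy archives holding both parameter sets,
  specs, scaler states, variant tag, history and a schema hash; loading
  verifies the hash and the variant before the model can touch data.
- The "power spectrum" peripheral feature is the periodogram sum excluding
  DC, so a constant signal reports zero power.
- Known limitations: the critic keeps dropout 0.5 even in the Wasserstein
  variants (kept for architectural fidelity, though unusual for critics);
  weight clipping for CWGAN uses the classic ±0.01 and can under-train the
  critic on wide inputs; the GraffitiVR composite EEG indices are opaque
  pass-through columns.
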