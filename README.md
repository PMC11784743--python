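# hatl — cross-modal EEG synthesis for faster BCI calibration

EEG-based emotion recognition needs a long per-user calibration session
before its classifiers work, which is impractical for children, patients and
VR applications. Non-EEG sensors — eye trackers, peripheral physiology
(EOG/EMG/GSR/respiration/plethysmograph/skin temperature), head-movement
tracking — calibrate much faster. `hatl` implements *heterogeneous
adversarial transfer learning*: a conditional adversarial network learns,
from a pool of previously recorded subjects, to map non-EEG feature vectors
(plus an emotion label and noise) to EEG band-feature vectors. For a new
subject, EEG is then **synthesized** from their cheap non-EEG calibration
data, and the emotion classifiers are trained on the synthetic fusion —
cutting the calibration session down to the non-EEG recording.

## The model

Three conditional variants share one architecture. The generator G consumes
`[z, s, y]` (noise, non-EEG features, one-hot label) through residual blocks
(linear → batch norm → ReLU, output concatenated to input); the
discriminator/critic D consumes `[x, y]` through
linear → LeakyReLU(0.2) → dropout(0.5) layers:

- **CGAN** — saturating cross-entropy objective,
  `min_G max_D  E[log D(x,y)] + E[log(1 − D(G([z,s,y]), y))]`;
- **CWGAN** — Wasserstein surrogate `E[D(x,y)] − E[D(G([z,s,y]), y)]`
  with weight clipping;
- **CWGAN-GP** — the same plus a gradient penalty
  `λ E[(‖∇_x̂ D(x̂,y)‖₂ − 1)²]` on interpolates x̂ between real and
  generated samples (λ = 10).

Both networks train with Adam (lr 2·10⁻⁴, betas (0.5, 0.9), weight decay
10⁻⁶) for 100 epochs on min–max-scaled features. The networks run on a
small in-package autodiff engine (numpy) that supports the double
backpropagation the gradient penalty requires.

Fidelity of generated EEG is scored by row-wise Euclidean distance, the
1-D empirical Wasserstein distance, a histogram KL divergence and Welch's
t-test, per EEG band. Downstream value is measured by a leave-one-subject-out
(LOSO) benchmark: an SVM + random-forest + MLP ensemble is calibrated per
held-out subject under five conditions (non-EEG only, each GAN variant's
synthetic fusion, real-EEG fusion) and tested on the subject's real
recordings. Calibration savings are summarised by the calibration
improvement score `CIS = (1 − B/A)·100%`.

Three dataset-family feature schemas ship built in: 62-channel × 5-band EEG
with 33 eye-movement features and five emotion classes (310 + 33 dims);
32-channel × 4-band EEG with 64 peripheral features and four
valence–arousal quadrants (128 + 64); 6-channel VR EEG with composite
indices and 15 head-movement features (35 + 15). Real recordings of those
datasets are licensed, so the package includes a latent-factor simulator
whose `coupling` parameter controls exactly how much EEG structure the
non-EEG modality carries.

## Worked example

```python
from hatl import SimConfig, TrainConfig, simulate_multimodal_features
from hatl.harness import run_loso

ds = simulate_multimodal_features(SimConfig(seed=0))   # 3 subjects, coupled
result = run_loso(ds, conditions=("noneeg", "cwgan-gp", "real"),
                  gan_config=TrainConfig(epochs=100), seed=0)
for cond in result.conditions:
    print(f"{cond:>9}: accuracy {result.grand_mean(cond):.3f} "
          f"+/- {result.grand_std(cond):.3f}")
print("generated vs real: %.1f%%" % result.ratio_vs("cwgan-gp", "real")[0])
```

prints

```
   noneeg: accuracy 0.517 +/- 0.041
 cwgan-gp: accuracy 0.528 +/- 0.041
     real: accuracy 0.565 +/- 0.035
generated vs real: 93.4%
```

Classifiers calibrated on synthetic EEG fall between the non-EEG-only
baseline and real-EEG calibration, recovering most of the real-EEG accuracy
without collecting any EEG from the held-out subject. The `examples/`
scripts walk through each stage (simulation, GAN training and fidelity,
LOSO benchmark, calibration sweep, raw-signal feature extraction), and the
`hatl` command line mirrors them (`hatl simulate | extract | train-gan |
synthesize | fidelity | run-loso | sweep-calibration | report`).

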