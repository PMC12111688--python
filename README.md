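# emokan

Sparse-channel EEG emotion recognition with a CNN–KAN classifier and an
FFT-based frequency-channel attention block.

Wearable EEG headsets expose only a handful of frontal electrodes, so
emotion-recognition pipelines built for 32- or 62-channel laboratory caps do
not transfer to them. `emokan` implements a complete recognition pipeline
for the four frontal channels **FP1, FP2, AF3, AF4**: band-limited feature
extraction, baseline-based individual-difference correction, a pseudo-RGB
feature image, and a compact convolutional classifier whose head is a
Kolmogorov–Arnold (B-spline) layer gated by frequency-channel attention.
The whole pipeline is testable end to end on synthetic EEG; adapters for
the DEAP and SEED distributions are included for users with access to
those datasets.

## Method

For every 1-s window and each band *b* ∈ {θ (4–8 Hz), α (8–13), β (13–30),
γ (30–45)} the package computes four feature families:

- **Band power (PSD)** — the Welch spectral density integrated over the
  band, `P_b = ∫_{f1}^{f2} PSD(f) df`;
- **Differential entropy (DE)** — `DE = ½ ln(2πe σ²)` of the band-filtered
  signal under a Gaussian assumption;
- **EVI** — `ln(P_θ,ch1 / P_θ,ch2)`, the inter-hemispheric theta log-ratio
  over the pairs FP1–FP2, AF3–AF4, FP1–AF4, AF3–FP2;
- **ASI** — `(P1 − P2)/(P1 + P2) ∈ [−1, 1]` for α, β, γ over the same pairs.

Features are min-max normalised to [0, 1] (ranges fitted on the training
split of each fold) and the mean of each trial's normalised 3-s baseline is
subtracted, bounding corrected features in [−1, 1] and removing per-subject
offsets. The 48 features fill a 4×4×3 *pseudo-RGB image* (planes DE / PSD /
EVI-ASI; rows bands, columns channels or pairs).

The classifier is a three-layer 3×3 CNN (32/64/64 filters, batch-norm,
dropout 0.5/0.4/0.3). On the final 4×4×64 map, the **F2CA** block pools each
channel, takes the real part of a full-length DFT of the pooled vector,
passes it through a sigmoid-gated bottleneck (ratio 8), and rescales the
channels. The dense-256 embedding then feeds a **KAN layer** (SiLU base path
plus per-edge cubic B-splines on a uniform grid over [−1, 1] with a
learnable spline scaler) and a softmax head. Four ablation variants are
provided (`cnn`, `cnn_fcn`, `cnn_kan`, `cnn_kan_f2ca`); the first two total
exactly 320,388 and 352,772 parameters at four classes, and inserting F2CA
adds exactly 1,096. Training uses Adam (lr 5e-4, batch 512, L2 1e-3) under
seeded 10-fold cross-validation with support-weighted precision/recall/F1.

The network, including backpropagation and Adam, is implemented directly in
NumPy — the model is small enough (≈520k parameters on 4×4×3 inputs) that
BLAS matmuls train it in minutes on one CPU core.

## Worked example

```python
from emokan import EmotionClassifier, TrainConfig, simulate_dataset
from emokan.synth import default_four_class_config

trials = simulate_dataset(default_four_class_config(), n_trials_per_class=10, seed=2024)
clf = EmotionClassifier.from_trials(trials, variant="cnn_kan_f2ca",
                                    epochs=30, folds=10, seed=2024)
res = clf.fit()
print(res.summary())
```

```
Emotion classification — cross-validation results
==========================================================
variant: cnn_kan_f2ca    classes: HVHA, HVLA, LVHA, LVLA
folds: 10    epochs: 30    seed: 2024
----------------------------------------------------------
fold  n_test      acc     prec      rec       f1
   0     240   0.9833   0.9834   0.9833   0.9833
   1     240   0.9792   0.9797   0.9792   0.9792
   2     240   0.9958   0.9959   0.9958   0.9958
   3     240   1.0000   1.0000   1.0000   1.0000
   4     240   0.9875   0.9882   0.9875   0.9875
   5     240   0.9833   0.9835   0.9833   0.9834
   6     240   0.9833   0.9836   0.9833   0.9833
   7     240   0.9792   0.9794   0.9792   0.9792
   8     240   0.9833   0.9837   0.9833   0.9833
   9     240   0.9792   0.9799   0.9792   0.9793
----------------------------------------------------------
mean     accuracy 0.9854 ± 0.0071   f1 0.9854 ± 0.0071
```

Each fold trains on 2,160 of the 2,400 one-second windows and reports
accuracy and support-weighted precision/recall/F1 on the held-out 240; the
mean ± SD line summarises the 10 folds. On this strongly separable
synthetic configuration the classifier recovers the four classes almost
perfectly, while refitting on label-shuffled data scores at the 25% chance
level — the pipeline learns class structure, not bookkeeping artifacts.

A thin CLI mirrors the library: `emokan simulate`, `emokan train`,
`emokan evaluate` (see `--help`).

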