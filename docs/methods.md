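# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `emokan`, and what the synthetic experiments do and do
not demonstrate.

## Signal model and features

All features are computed on 1-s windows of the four frontal channels FP1,
FP2, AF3, AF4. Band edges are θ 4–8, α 8–13, β 13–30, γ 30–45 Hz —
consistent with source recordings that are band-limited to 4–45 Hz — and
are configurable on `Band`/`FeatureExtractor`.

- **Band power** uses the Welch estimator (Hann window, segment length
  `min(n, 256)`, 50% overlap; a 1-s window at 128 Hz is a single segment)
  with density scaling, integrated over half-open bins `[f_low, f_high)` so
  that adjacent bands partition the spectrum without double counting. The
  PSD *feature* is this band-integrated power (µV²), not the density curve.
- **Differential entropy** is `½ ln(2πe σ²)` in nats (natural log
  throughout, which is what the 2πe form implies), where σ² is the sample
  variance after a zero-phase 4th-order Butterworth band-pass
  (`sosfiltfilt`, so no group delay).
- **EVI** is the natural-log theta-power ratio and **ASI** the normalised
  power difference, both over the four pairs FP1–FP2, AF3–AF4, FP1–AF4,
  AF3–FP2. The same four pairs are reused for ASI in α/β/γ.
- Zero-variance or zero-power windows raise `DegenerateSignalError` rather
  than returning −∞/NaN; callers are expected to skip such windows.

Feature order is canonical everywhere: blocks (DE | PSD | spatial), each
block band-major and channel/pair-minor; the spatial block is 4 theta-EVI
values followed by 12 ASI values. `feature_names()` is the single source of
truth and the pseudo-RGB layout map is tested as a bijection against it.

## Individual-difference correction

Per trial, the first 3 s are the baseline, cut into 1-s windows like the
experimental remainder. The order of operations is: min-max normalise all
features to [0, 1], then subtract the per-trial mean of the *normalised*
baseline features. Corrected values are therefore bounded in [−1, 1], which
in turn bounds the KAN spline grid domain.

Normalisation scope is a genuine design choice (per subject, per trial and
global are all defensible): ranges are fitted per cross-validation fold on
the training split only (training windows plus the baselines of their
trials) and applied to held-out data with clipping, preventing leakage.
Each `MinMaxNormalizer` carries a `fitted_on` tag so fold provenance is
checkable. A whole-dataset ("global") fit is available for parity
experiments and for standalone HDF5 exports from the CLI. Constant feature
columns map to 0 and emit a warning. Baseline windows never enter training;
they only supply the per-trial mean.

## Architecture

Backbone: three 3×3 same-padding convolutions with 32, 64, 64 filters
(no pooling, so the 4×4 geometry is preserved and flatten = 1024), each
followed by batch-norm, ReLU, dropout (0.5, 0.4, 0.3); then dense 256
(ReLU) and dropout 0.5. Heads: `cnn` — dense to classes; `cnn_fcn` — dense
128 then classes; `cnn_kan(_f2ca)` — KAN(256→128) then classes. The conv →
BN → ReLU → dropout order is our choice where reasonable alternatives
exist. Parameter counting includes batch-norm moving statistics (4 values
per channel), the convention under which the four-class `cnn` variant
decomposes exactly as 896 + 18,496 + 36,928 + 640 + 262,400 + 1,028 =
320,388.

**F2CA.** Global average pooling gives a length-C channel descriptor; the
attention input is the real part of its *unnormalised, full-length* DFT
(length preserved, so the bottleneck weight is C × C/r; with biases in
both layers the block adds exactly 1,096 parameters at C=64, r=8 — the
choice of full-length transform and biases is the only one consistent with
that delta). Whether to scale the DFT by 1/C is a convention; the
unnormalised transform is used and the matrix is kept in float64 for
descriptor accuracy. The block sits after the third convolution, on the
4×4×64 map, and its sigmoid gate guarantees |output| ≤ |input| elementwise.

**KAN layer.** Output = `SiLU(X)·W_base + Σ_i scaler[i,o]·Σ_k B_k(x_i)·
W_spline[i,o,k]`. The B-spline basis is cubic (order 3) on a uniform grid
of 5 intervals over [−1, 1], extended by `order` knots per side, giving
`grid_size + order = 8` basis functions and `d_in·d_out·(2 + grid + order)`
parameters. Inputs outside the span are clamped before basis evaluation
(avoiding zero-basis dead zones; the clamp zeroes the spline path's input
gradient there while the SiLU path still flows). The grid is not adapted
during training. Spline coefficients start small (σ = 0.1/√d_in) and the
scaler at 1, so the layer begins near its linear base path. The grid and
order behind the reference CNN-KAN parameter total are not recoverable from
that total alone; these defaults do not attempt to reproduce it.

**Group fusion.** `fuse_group` and the `MeanFusion`/`GroupConcat` layers
implement averaging (or concatenating) the dense-256 embeddings of a group
of consecutive windows before the head. The default protocol trains
window-level (`group_size=1`): the cross-validation split is defined at the
window level, and the permutation-null control needs window-level sample
counts for statistical power. Grouped training is available via
`ModelConfig(group_size=12)`.

## Training and evaluation

Adam (β₁ 0.9, β₂ 0.999, ε 1e-7), learning rate 5e-4, batch 512,
cross-entropy plus an L2 penalty of 0.001 on kernel weights (conv, dense,
F2CA and KAN base/spline weights; biases, batch-norm and spline scalers are
exempt). Batch-norm momentum is 0.9 so the moving statistics converge
within the short schedules used on desk-scale data (tens of epochs; with
0.99 the inference-time statistics lag badly after ~150 steps). No early
stopping. K-fold splitting is seeded and shuffled; each fold trains a fresh
model (seed = base seed + fold) and a fresh normaliser. Metrics are
accuracy and support-weighted one-vs-rest precision/recall/F1; weighted
recall equals accuracy for single-label problems, which is asserted in the
tests. Both the 10-fold protocol and an 8:1:1 holdout (`fit_holdout`) are
provided; cross-validation is the default. A documented limitation of the
window-level protocol: windows of one trial can land in different folds, so
within-trial correlation inflates absolute accuracies; a trial-grouped
split would be stricter.

The whole network stack (conv via im2col, batch-norm, dropout, F2CA, KAN,
Adam, backprop) is NumPy/BLAS in float32. Gradient correctness is checked
against central finite differences through every layer type.

## Synthetic data

`simulate_trial` emulates the public datasets' trial structure: a 3-s
class-neutral baseline followed by a 60-s experimental segment at 128 Hz
(63 s total). Each channel is a sum of four unit-variance narrow-band noise
oscillations (θ/α/β/γ, amplitudes 4/5/4/3 µV) and a 1/f (exponent 1)
background band-limited to 4–45 Hz. The background-to-oscillation ratio is
set so the aperiodic component dominates (SNR 0.5), as it does in resting
EEG; under this choice a 3× channel gain in α (9× in power, analytic
asymmetry 0.8) measures as an ASI of roughly 0.45 after attenuation by the
in-band background. Class identity is encoded by multiplicative band gains
— the default four-class preset uses opposite α lateralisations for two
classes and global β / γ (+θ-lateralised) power for the other two — because
the features are power-based; phases are randomised per trial, and
everything is deterministic given (class, config, seed).

What this generator does *not* emulate: eye-blink and muscle artifacts,
non-stationary drifts, volume-conduction correlation between channels,
subject-specific spectra beyond the baseline offset, and realistic
(weak, overlapping) class effects. Passing the end-to-end test therefore
shows that the pipeline's plumbing, correction and classifier can recover
class structure that is present in band power and asymmetry — not that
comparable accuracy would be reached on real recordings.

## Reference experiment sizes

The canonical synthetic experiment uses 4 classes × 10 trials (2,400
experimental windows, matching the protocol's reference problem size),
`cnn_kan_f2ca`, 30 epochs, 10-fold CV, and a second run on label-shuffled
data as a permutation null. These sizes keep a full double cross-validation
in the minutes range on one CPU core while leaving per-fold test sets of
240 windows. The baseline-centring check uses 24 class-neutral trials
because the 3-window baseline mean is itself noisy with σ ≈ 0.09 per trial;
only averaging across trials brings the dataset-level mean inside ±0.05.

## Known limitations

- The published benchmark accuracies on DEAP/SEED are not reproduction
  targets here: both datasets are license-gated, so the adapters are tested
  on synthetic fixtures written in the same layouts.
- Window-level cross-validation (the source protocol) is optimistic for
  subject generalisation; no subject-wise split mode is implemented.
- The NumPy backend trains single-threaded; 200-epoch full-scale runs are
  possible but slow, and no GPU path exists.
- Min-max normalisation is sensitive to outlier windows (ranges, not
  robust quantiles); degenerate columns are flagged but not imputed.
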