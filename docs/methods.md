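# Methods

## Estimation model

The estimator maps a standardized sensor window S_in (t × 20) to a scalar
target (EE in kcal/min or HR in bpm) through four stages.

**Channel-wise attention.** O = σ(S_in·W_in + b_in), Att = time-mean of O,
S_att = Att ⊗ S_in. W_in is 20 × 20; the bias is one value per *channel*
broadcast over time. A per-time-step bias would tie the layer to a fixed
window length and is shape-inconsistent with broadcasting over t × i, so the
per-channel form is used; this keeps the layer window-length independent.
Att lies strictly in (0, 1) (sigmoid range) and the ratio S_att/S_in per
channel is constant over time and equals Att. Forcing Att = 1 is exactly the
no-attention ablation, which the implementation also exposes as a bypass.

**1-D DenseNet.** Stem convolution (kernel 7, stride 2), then dense blocks
of pre-activation BatchNorm → ReLU → conv(kernel 3) layers whose outputs are
concatenated with their inputs along the channel axis (growth rate g per
layer); transitions between blocks apply a 1-wide conv with compression 0.5
and stride-2 average pooling. There is no global pooling at the end: the
output is a T × c1 feature sequence. The published description leaves depth,
growth and kernel sizes open; the default here (3 blocks × 4 layers,
g = 12, initial channels 24) is the smallest standard DenseNet shape that
keeps T ≥ 20 for a 333-sample window (T = 41, c1 = 90). All of it is
configurable; output shapes follow closed-form arithmetic implemented in
`feature_channels` / `temporal_length` and are property-tested.

**Bi-GRU.** Gates act on the concatenation [h_{t−1}, x_t] with no gate
biases, exactly as the update equations are printed: r and z by sigmoid, the
candidate by tanh of the reset-gated state, and the convex blend
h_t = (1−z)·h_{t−1} + z·h̃_t. (The accompanying prose swaps the names of the
reset and update gates relative to the equations; the equations are
implemented as printed.) Forward and backward passes are concatenated per
aligned time step, so the output width c2 is twice the per-direction hidden
size (default 32 per direction, c2 = 64). Whether the published c2 denotes
per-direction or post-concatenation width is ambiguous; post-concatenation
is used here.

**GAP head.** Prediction = mean over time of (h_t·W_out + b_out), which by
linearity equals the projection of the time-averaged hidden state — both
identities are tested.

## Training

Adam (lr 1e-3), batch 16, MSE loss, up to 150 epochs with early stopping:
"no significant improvement" is operationalized as the validation MSE
failing to undercut the best-so-far by ≥ 1e-4 for 20 consecutive epochs
(both thresholds configurable); the best-epoch weights are restored.
Evaluation is leave-one-subject-out (LOSO): one fold per subject, trained on
the rest. LOSO defines only train/test, so for early stopping one randomly
chosen (seeded) *training* subject is carved out as validation — the
subject-level split mirrors the LOSO philosophy. The channel standardizer
(per-channel z-score, population-std convention) is refitted per fold on
training subjects only; the held-out subject never influences
standardization or early stopping, and this is asserted in tests.

Labels are z-scored on the training split and predictions are inverted back
to label units. This is purely numerical conditioning: GRU states are
bounded, so an unscaled HR target (~70–170 bpm) would force extreme readout
weights; metrics are always reported in bpm / kcal/min. Training-window
order is reshuffled each epoch from the run seed; validation and test are
never shuffled. All computation is float64 on one CPU, so a fixed seed
reproduces weights, predictions and attention matrices bit for bit.

The network runs on a compact reverse-mode autodiff engine written for this
package (`insolenet.nn`): ~15 differentiable operations over numpy arrays,
with the GRU fused into a single hand-derived backprop-through-time
operation for speed. Gradients are verified against central finite
differences, and the fused GRU against an independent step-wise
implementation.

## Preprocessing

Sparse HR/EE labels are linearly interpolated onto the sensor clock (exact
at knots; grid points outside the label span are clamped to the end values
with a warning), then windows of round(10 s × fs) = 333 samples are cut
every round(1 s × fs) = 33 samples; each window's label is the mean of the
interpolated label over the window. The window count is the exact function
floor((D − W)/H) + 1 of the recording duration. "Overlapped by 1 s" is read
as hop = 1 s (adjacent windows share 9 s), which gives ~1 window per second
of recording — consistent with the reported dataset sizes at full scale.

## Evaluation statistics

RMSE, MAE, R² and MAPE follow their textbook definitions (MAPE stored as a
fraction, displayed ×100). Bland–Altman differences are *estimated minus
actual*, so a positive mean error means over-estimation; limits of agreement
are ME ± 1.96·SD with the sample (n−1) SD, the standard Bland–Altman
practice. The attention-vs-ablation comparison pairs per-subject metrics and
uses a one-tailed paired t-test (alternative: attention better). When every
per-subject difference is zero the t-statistic is 0 and p is reported as
0.5; a nonzero constant difference yields p → 0 or 1 by its sign.

## Sensor ranking

Each test-set window contributes one attention vector; pooled across folds,
the 20 channels form the groups of a fixed-effects one-way ANOVA (the
published within-group degrees of freedom imply per-observation weights
rather than per-subject means, so the per-window unit is used). Tukey HSD
pairwise p-values come from the studentized-range distribution with standard
error sqrt(ms_within/2 · (1/n_a + 1/n_b)) — the harmonic-mean convention for
unequal sizes, which only arises in axis pooling. Homogeneous subsets are
maximal runs of mean-sorted channels whose pairwise p-values all exceed α;
overlapping subsets are allowed (staircase-table convention) and each subset
reports its extreme-pair p. The axis comparison pools the accelerometer and
gyroscope channels by axis (4 channels each for x, y, z; pressure excluded)
and runs the same ANOVA + Tukey machinery over three groups.

## The gait simulator

The simulator's realism target is statistical, not biomechanical: it must
make exercise intensity recoverable from the channels with *planted,
unequal* informativeness so that attention-based ranking has a ground
truth. Defaults mirror the study conditions: 10 subjects, 33.3 Hz, a 3→10
kph ramp (+1 kph per stage; 120-s stages, i.e. 16 min, at full scale),
labels every U(2, 5) s. Per-foot stride phase advances at cadence(v)/2
strides per minute with the feet anti-phased; cadence(v) = 70 + 9·v
steps/min spans ~97 (3 kph walk) to ~160 (10 kph run). Pressure channels
emit raised-cosine stance bumps ordered heel → 4th metatarsal head → 1st
metatarsal head → toe within each stride; IMU channels are two stride-locked
harmonics. Every channel's amplitude is coupling[c] × (0.5 + 0.15·v).

HR follows dHR/dt = (hr_rest + hr_gain·v − HR)/τ from HR(0) = hr_rest
(exact exponential stepping at 0.05 s; defaults hr_rest 70 bpm, gain
9 bpm/kph, τ 30 s). EE is ee_base + ee_gain·v plus AR(1)-smoothed noise
(defaults 1.2 kcal/min, 1.0 kcal/min per kph — about 2–12 kcal/min over the
ramp). Subject heterogeneity is a mild lognormal jitter (cv ≈ 10%) around
these means, echoing a physically homogeneous cohort.

**Couplings and noise.** Default couplings are 3.0 on the four vertical
(z-axis) IMU channels, 1.0 on the other IMU axes and 1.5 on pressure.
Channel noise is additive Gaussian with sd 2.0: against waveform amplitudes
of roughly 1–2 (weak channels) this puts the 1×-coupled channels in the
noise-dominated regime (variance-SNR ≈ 0.1–0.5) while the 3× z channels stay
signal-dominated (SNR ≈ 1–4.5). This separation is what "planted, unequal
informativeness" means operationally: after per-channel z-scoring all
channels have unit variance, so informativeness differences must live in the
signal-to-noise ratio, not the scale.

**What the simulator does not model** — and what passing tests therefore do
not show about real data: ground-reaction-force biomechanics, sensor drift
and saturation, non-stationary gait (overground running, turns), label
noise structure of real calorimetry, and physiological coupling between HR
and EE beyond their shared speed dependence. Recovery of the planted
channels demonstrates that the attention mechanism ranks sensors by
informativeness under controlled conditions; it does not certify the
published human-cohort rankings.

## Desk-scale problem sizes

End-to-end checks run on one CPU with a reduced — never truncated —
protocol: 10 subjects × 240 s (full 3→10 kph ramp, 30-s stages), 10-s
windows with a 5-s hop (~47 windows/subject), a small network
(stem stride 4 → T = 21, 3 blocks × 2 layers, growth 8, c1 = 32, hidden 32),
at most 12 epochs with patience 5, and 3 of the 10 LOSO folds. These sizes
are the package's chosen compromise between statistical resolution and
run time; `insolenet.experiments` pins them so that the test suite and the
reproduction script report the same experiment. Null-calibration runs use
the same cohort with all couplings equal and a single fold per seed.

## Known limitations

- Attention weights move only ~0.01 from their 0.5 initialization at desk
  scale; rankings are read from small differences and need the ANOVA/Tukey
  machinery (not raw inspection) to be meaningful.
- Attention under a true null (equal couplings) is not exchangeable across
  channels: training drifts per-channel attention means apart (~0.003 on the
  0-1 scale, versus ~0.001 from random initialization alone) in ways
  unrelated to the couplings, while within-channel variance across windows
  is tiny (each attention value is already an average of 333 sigmoids). The
  pooled per-window ANOVA therefore rejects essentially always, null or
  not — it should be read as licensing the post-hoc Tukey ranking, not as a
  calibrated significance test of "do the sensors differ at all". The
  standalone ANOVA implementation is calibrated (type-I error 5% ± 2% on
  exchangeable Gaussian groups); the miscalibration is a property of
  attention weights as observations, not of the statistics.
- The full-scale configuration (150 epochs, hop 1 s, 16-min protocol, 10
  folds) is implemented and configurable but not exercised by the test
  suite; desk-scale results are qualitative analogues, not reproductions,
  of full-scale numbers.
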