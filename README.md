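# insolenet

Energy-expenditure (EE, kcal/min) and heart-rate (HR, bpm) estimation from a
20-channel smart-shoe sensor array, with attention-based sensor ranking.

## The problem

Instrumented insoles carry, per foot, four plantar-pressure sensors plus a
triaxial accelerometer and gyroscope — 20 channels sampled at a nominal
33.3 Hz while the wearer walks or runs. Two physiological targets are
recorded sparsely (every ~2–5 s) alongside: EE from indirect calorimetry and
HR from a chest strap. The questions this package answers for wearable-signal
researchers are:

1. **Estimation** — how well can EE and HR be regressed directly from the raw
   multichannel signal, with no hand-crafted features, in a
   leave-one-subject-out (LOSO) evaluation that measures inter-subject
   generalization?
2. **Sensor selection** — *which* of the 20 channels carry the information?
   A channel-wise attention layer learns a per-channel weight in (0, 1);
   one-way ANOVA and post-hoc Tukey HSD homogeneous subsets over the
   per-window attention vectors rank the sensors.

## The model

For an input window S<sub>in</sub> ∈ R<sup>t×i</sup> (t = 333 samples ≈ 10 s,
i = 20 channels):

- **Channel-wise attention**: O = σ(S<sub>in</sub>W<sub>in</sub> + b<sub>in</sub>),
  Att = mean<sub>t</sub>(O) ∈ (0,1)<sup>i</sup>,
  S<sub>att</sub> = Att ⊗ S<sub>in</sub> (channel-wise product).
- **1-D DenseNet**: stem convolution, then dense blocks in which each layer's
  output is concatenated with its input along the channel axis; transition
  layers compress channels (×0.5) and average-pool time. No global pooling at
  the end — the output is a feature *sequence* F<sub>dense</sub> ∈ R<sup>T×c₁</sup>.
- **Bi-GRU**: r<sub>t</sub> = σ(W<sub>r</sub>[h<sub>t−1</sub>, x<sub>t</sub>]),
  z<sub>t</sub> = σ(W<sub>z</sub>[h<sub>t−1</sub>, x<sub>t</sub>]),
  h̃<sub>t</sub> = tanh(W<sub>h</sub>[r<sub>t</sub>∗h<sub>t−1</sub>, x<sub>t</sub>]),
  h<sub>t</sub> = (1−z<sub>t</sub>)∗h<sub>t−1</sub> + z<sub>t</sub>∗h̃<sub>t</sub>,
  run forward and backward and concatenated per step (width c₂ = 2·hidden).
- **GAP head**: prediction = (1/T) Σ<sub>t</sub> (h<sub>t</sub>W<sub>out</sub> + b<sub>out</sub>).

Training: Adam (lr 10⁻³), batch 16, MSE loss, early stopping (patience 20 of
150 epochs at full scale) on a held-out validation subject, best weights
restored. One model per target. The ablation arm bypasses the attention
layer; forcing Att = 1 reproduces it exactly.

The network and its training run on a small numpy reverse-mode autodiff
engine included in the package (`insolenet.nn`) — float64, single-threaded,
bit-reproducible from a seed, no deep-learning framework dependency.

Because the original participant recordings are not public, the package
bundles a treadmill-gait **simulator** (`insolenet.simulate`) that generates
cohorts with a 3→10 kph speed ramp, cadence- and amplitude-modulated gait
waveforms, first-order-lag HR dynamics, a linear EE–speed relation, and
*known* channel-to-intensity couplings (strongest on the vertical-axis IMU
channels by default), so estimation and sensor-ranking behaviour can be
validated against planted ground truth.

## Worked example

```python
from insolenet.experiments import run_small_study, attention_z_vs_rest
from insolenet.evaluation import summarize_folds
from insolenet.importance import rank_sensors

folds = run_small_study(seed=1)          # 10 subjects x 240 s, 3 LOSO folds
print(summarize_folds(folds))
print(attention_z_vs_rest(folds))
print(rank_sensors(folds)["report"].head(6))
```

prints (seed 1, under a minute on one CPU):

```
{'rmse': (0.444, 0.04), 'mae': (0.35, 0.031), 'r2': (0.961, 0.008)}
(0.50489, 0.4977)
  channel  mean_attention subsets
0    A_LZ        0.506741     [9]
1    G_LZ        0.506409     [9]
2    A_LX        0.506068  [8, 9]
3    A_LY        0.503374     [8]
4    G_RZ        0.503252  [7, 8]
5    A_RZ        0.503139  [7, 8]
```

Read: the EE estimator reaches R² ≈ 0.96 on held-out subjects; the mean
attention weight over the four planted vertical-axis IMU channels (0.5049)
exceeds the mean over the other sixteen (0.4977); and the sensor ranking
places those channels (A_LZ, G_LZ, G_RZ, A_RZ) in four of the six top
positions, with the two z channels of the left shoe alone in the highest
Tukey homogeneous subset.

The same pipeline is available from the shell. Default configs are the
full-scale protocol (16-min recordings, 150 epochs, 1-s hop) — for a quick
desk-scale run pass overrides, e.g.:

```bash
cat > cohort.yaml <<'YAML'
protocol: {stage_seconds: 30}
YAML
cat > train.yaml <<'YAML'
max_epochs: 12
early_stop_patience: 5
hop_s: 5.0
densenet: {initial_channels: 16, growth_rate: 8, layers_per_block: 2,
           n_blocks: 3, stem_stride: 4}
YAML
insolenet simulate --config cohort.yaml --seed 1 --out data/
insolenet train data/ --config train.yaml --target ee --seed 1 --out runs/ee_att
insolenet train data/ --config train.yaml --target ee --no-attention --seed 1 --out runs/ee_abl
insolenet report runs/ee_att runs/ee_abl --out tables/
```

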