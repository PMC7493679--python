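# Methods

## The problem and the overall design

The package studies how much gender information different learners can
extract from skeletal gait, contrasting a *sequence* classifier (an LSTM
fed the temporal evolution of joint trajectories) with *static* learners
(SVMs and a random decision forest fed order-free summaries). Because the
kind of motion-capture cohort this requires — tens of adults walking on a
treadmill, recorded as 20-joint 3D trajectories at 24 fps — is rarely
shareable under privacy constraints, the cornerstone of the package is a
parametric synthetic walker whose gender cues are *planted and therefore
known*. Every downstream claim (metric recovery, null calibration, cue
ordering) is checked against the generator's ground truth rather than
against an unverifiable dataset.

## The synthetic walker

Each walker is a 20-joint kinematic chain (head, neck, mid-spine, pelvis,
and left/right shoulder–elbow–wrist–hand and hip–knee–ankle–foot) driven by
low-order periodic functions of the gait phase `u ∈ [0, 1)` at stride
period `P`:

* pelvis lateral sway `A_hip · sin(2πu)`; vertical bounce at twice the
  stride frequency; shoulder girdle counter-sway `A_sho · sin(2πu + π)`;
* legs a half-cycle apart; each arm in antiphase with its ipsilateral leg,
  swing amplitude in radians with a fixed 0.35 rad elbow bend;
* the anterior–posterior trend of the pelvis is identically zero — the
  treadmill convention (the walker faces the viewer).

The legs do **not** follow a single sinusoid. During stance (duty factor
`d`, default 0.62 of the cycle) the foot travels backward at constant
velocity, emulating the treadmill belt; during swing it returns with a
cosine ease while knee flexion `β(u)` rises to `knee_flexion_max`
mid-swing (a quarter-amplitude bump during stance), shortening the
effective hip–ankle link and producing foot clearance through two-link
geometry. This piecewise profile is what makes the clinical metrics
analytic:

| quantity | closed form |
|---|---|
| cadence (steps/min) | `120 / P` |
| speed (m/s) | `stride / P` |
| fore-aft foot excursion (treadmill frame) | `stride × d` |
| single / double support | `2(1−d)` / `2d−1` |
| stance:swing per leg | `d / (1−d)` |
| mean swing knee flexion | `β_max · 2/π` |

Segment lengths are stature fractions from standard biomechanics segment
tables; per-coordinate i.i.d. Gaussian jitter (default 5 mm) emulates
consumer depth-sensor noise.

### Planted gender cues

Two separable channels, each a truncated-Gaussian effect in
`EffectConfig`:

* **dynamic** — the shoulder/hip sway-amplitude ratio, mean 1.3 (M) vs
  0.7 (F), SD 0.25;
* **structural** — shoulder:hip width ratio 1.15 vs 0.95, and stature
  drawn from the study population's gender means/SDs.

`dynamics_only()`, `structure_only()` and `null()` configurations isolate
the channels; cycle period, stride length, bounce, arm swing, knee
flexion and the duty factor are gender-neutral by default so that the
clinical metrics carry no planted gender signal under `dynamics_only()` —
the property the planted-effect ordering tests rely on. The default cycle
period is 1.6 s (cadence 75 steps/min, a slow treadmill pace consistent
with a 0.4 s quarter-step reading of the protocol's shortest exposure).

### What the generator does not emulate

Real gait variability is richer: stride-to-stride timing jitter, asymmetry,
sensor occlusion and tracking dropouts, anthropometric covariance beyond
stature scaling, and overlapping gender distributions on many correlated
cues. Consequently, absolute accuracies on synthetic cohorts are not
comparable to accuracies on real cohorts; only *relative* statements
(orderings, trends, null behavior) transfer, and the test suite asserts
only those.

## Preprocessing

Height normalization rescales the skeleton by the median head-to-foot
vertical extent (one scalar; aspect preserved) and centers the mean pelvis
at the origin, removing stature as a cue. Velocity input is the forward
difference of adjacent frames after a 5-frame centered moving average
(shrinking windows at the edges); the last difference is repeated so
position and velocity windows align one-to-one. Coronal projection drops
the anterior–posterior axis (60 → 40 numbers per frame). Windows are
defined in frames — `10k` frames for `k = 1..10` — with the conventional
second labels (0.4 s steps) kept for reporting only, since 10 frames at
24 fps is 0.417 s. Feature scaling is z-score followed by min–max to
[−1, 1], both frozen from the training split; test values are not clipped.
Sequence inputs receive the z-score stage only. Standardization is
per-feature over the training set; alternative granularities were
considered and rejected as under-determined.

## Models

The LSTM is a single standard gated cell (input/forget/output gates, tanh
candidate, no peepholes) implemented in numpy with full backpropagation
through time: 128 hidden units, zero-mean Gaussian init (SD 0.1),
forget-gate bias +1, final hidden state → ReLU → affine → 2 logits →
softmax cross-entropy, Adam at learning rate 1e-3, batches of 50, 100
epochs, global gradient-norm clipping at 5. No early stopping, dropout or
schedules. The gate parameter count `4(H(D+H)+H)` is asserted against the
implementation. Cross-entropy is applied to softmaxed logits (the one-hot
regression reading was rejected).

Static models wrap scikit-learn: SVC with linear, RBF (γ = 0.99) and
sigmoid kernels at C = 1.0 (unstated, configurable), and a 10-tree forest
with entropy criterion, `min_samples_split=2`, at most 3 features per
split, majority vote. Entropy-threshold binary splits on continuous
features stand in for classic ID3, which has no native continuous-feature
rule.

## Gait events and clinical metrics

Heel strike is the local maximum of the foot's anterior position relative
to the pelvis (5-frame smoothed; minimum peak separation 0.4× the stride
period estimated from the pelvis-sway autocorrelation); toe-off is the
following minimum. The 12 metrics are stride length, cadence, speed,
stride time, single and double support, stance:swing per leg, and mean
knee flexion per leg in stance and swing. Walking speed is estimated from
the mean backward foot velocity over the interior 60% of stance (the belt
speed), which breaks the apparent circularity between stride length and
speed on a treadmill: stride = residual HS-to-HS displacement +
belt speed × stride time, and speed = cadence/120 × stride is then
self-consistent. Stride time is the 12th metric completing the named 11.

## Cross-validation and sweeps

Folds always partition subjects (gender-stratified `StratifiedKFold`), so
no walker contributes to both sides of a split. Each replicate re-seeds
model initialization and fold assignment; reported numbers are mean ± SE
over replicates. Windows are non-overlapping; `windows_per_session=1`
reproduces the one-prediction-per-session-per-duration design, which keeps
the sample size constant across durations — without it, short windows win
simply by outnumbering long ones. All cell seeds derive from one master
seed through `SeedSequence` spawn keys, making every sweep reproducible.

Two statistical readings deserve a note. First, the between-cohort F-test
is the variance-ratio construction `s²_A/s²_B` with `(n_A−1, n_B−1)`
degrees of freedom — the only reading consistent with cohort-sized df; a
Welch mean-comparison is available behind `mean_test=True`. Second, null
calibration (permuted labels) is run with one independent subject-level
permutation per replicate, folds stratified on the permuted labels, and
fold counts chosen so folds balance exactly (5 folds over 5+5 subjects).
A single shared permutation is genuinely learnable in a small cohort, and
imbalanced training folds bias constant-predicting kernels (RBF at
γ = 0.99 saturates on 240-dimensional inputs) deterministically below
chance — both are CV design artifacts, not model leakage, and the harness
avoids them by construction.

## Problem sizes

Full-protocol defaults (41 walkers, 6 × 60 s sessions) are practical for
offline runs. The test suite and analysis drivers use reduced conditions
chosen once: cohorts of 10–20 walkers with 2–3 sessions of 15–20 s,
window index k ∈ {1, 5, 10} where a grid is not the point, 3–10
replicates, and a 32-unit / 15–40-epoch LSTM variant for training-based
property checks (the 128-unit default is asserted structurally and
exercised in the unit tests). Point estimates under these conditions carry
sampling noise of a few percent; tests therefore assert orderings,
calibration bands and closed-form recoveries rather than absolute
accuracy levels.

## Known limitations

* The walker is kinematic, not dynamic: no ground-reaction forces, no
  inverse dynamics, no biomechanical validation.
* Event detection assumes treadmill (trend-free) data with visible
  fore-aft foot excursion; it refuses sequences without periodic pelvis
  sway rather than guessing.
* The RBF kernel at the fixed γ = 0.99 saturates on 240-dimensional
  4-stat inputs and tends to predict a constant class on held-out
  subjects; this is faithful to the specified hyperparameter, and shows up
  honestly in the sweep tables.
* Human psychophysics (observer accuracies) is out of scope; stimulus
  clips are exported as dot-coordinate tables, not rendered video.
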