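# gaitlab

Sequence versus static learning on skeletal gait: can a recurrent
(biomimetic) classifier exploit the *dynamic* cues of human walking —
lateral sway, velocity patterns — that order-free (non-biomimetic)
learners cannot see?

`gaitlab` is an analysis package for gender classification from 20-joint
3D gait trajectories (24 fps treadmill walking). Because motion-capture
cohorts of this kind are usually private, the package is built around a
parametric synthetic point-light walker whose gender cues are planted and
therefore known exactly, which turns every pipeline claim into a testable
statement against ground truth. It is aimed at researchers in movement
analysis and biological-motion perception who want a controlled sandbox
for comparing temporal and static gait representations.

## What is inside

| module | contents |
|---|---|
| `gaitlab.synthetic_gait` | kinematic-chain walker generator; gender-conditional cohorts (`EffectConfig`: dynamic sway cue, structural cue, or null) |
| `gaitlab.skeleton_io` | CSV session files (`t` + 60 coordinate columns), JSON sidecars, dataset manifests |
| `gaitlab.preprocessing` | height normalization, 5-frame smoothing, velocity differentiation, coronal (2D) projection, frame windows `10k, k=1..10`, train-frozen scaling |
| `gaitlab.features` | 4-statistic window summaries (min/max/mean/SD per dimension); heel-strike/toe-off detection; 12 clinical spatiotemporal metrics |
| `gaitlab.models` | numpy LSTM (128 hidden units, BPTT, Adam, softmax cross-entropy); SVM linear/RBF(γ=0.99)/sigmoid; 10-tree entropy forest |
| `gaitlab.experiments` | subject-wise stratified k-fold; duration sweeps over family × representation; point-light stimulus-clip export |
| `gaitlab.stats_report` | t-tests vs chance, variance-ratio F-tests, mean ± SE summaries, accuracy-vs-duration plots |

The model at the core is a standard single-layer LSTM: gates
`i, f, o = σ(·)`, candidate `g = tanh(·)`, state `c_t = f⊙c_{t−1} + i⊙g`,
`h_t = o⊙tanh(c_t)`, with the final hidden state passed through
ReLU → affine → softmax over the two gender classes. Its contrast class
is any learner fed `static_summary(w) = (min, max, mean, SD)` per
dimension — a representation provably invariant to frame order, which is
exactly the information the LSTM can use.

## Worked example

```python
import gaitlab as gl

# a cohort whose gender cue lives ONLY in sway dynamics
cohort = gl.sample_cohort(10, 10, seed=11,
                          effect=gl.EffectConfig.dynamics_only(),
                          sessions_per_subject=3, session_duration=20.0)
sessions = [(gl.generate_walk(s, 20.0, 24.0, seed=1000 + 10 * i + k,
                              session_id=f"sess{k}"), s.gender, s.subject_id)
            for i, s in enumerate(cohort.subjects) for k in range(3)]

from gaitlab.experiments import duration_sweep
from gaitlab.stats_report import replicate_accuracies
hp = gl.LstmHyperParams(hidden_size=32, epochs=40)   # reduced-scale variant
for rep in ("position3d", "velocity3d"):
    df = duration_sweep(sessions, "lstm", rep, ks=[5],
                        n_replicates=3, n_folds=3, seed=7, lstm_hp=hp)
    acc = replicate_accuracies(df, representation=rep)
    print(rep, acc.round(3))
```

prints (replicate accuracies on held-out walkers):

```
position3d [0.704 0.733 0.715]
velocity3d [0.815 0.704 0.859]
```

— the sequence model finds the planted sway cue well above the 50% chance
level, and velocity input (which strips static posture offsets and keeps
pure dynamics) helps. On the same cohort, static models trained on the 12
clinical gait metrics stay near chance, because cadence, speed, stride
and support fractions are gender-neutral by construction there:

```
svm_linear clinical [0.367 0.617 0.483]
```

The numbered drivers under `analysis/` run the full narrative at demo
scale — `01` materializes a cohort to disk, `02` validates clinical-metric
recovery against the generator's closed forms (zero-noise median relative
error < 1%), `03` sweeps exposure durations, `04` compares velocity and
2D/3D inputs with t/F statistics, `05` writes summary tables and the
accuracy-vs-duration figure — leaving their tables under `results/`.

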