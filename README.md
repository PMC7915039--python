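# grasplearn

Secure-grasp detection from an instrumented sensor glove and analysis of
agency-inspired feedback training.

`grasplearn` is a desk-scale, fully synthetic re-implementation of the
computational chain behind a glove-based motor-learning experiment.  A
sensor glove streams 10 voltage channels (5 force, 5 flex, one pair per
digit) at 40 Hz while a subject grasps objects with three grips
(precision pinch, tri-pod, whole-hand).  A per-subject feedforward
neural network learns to detect *secure grasp* — all engaged channels
holding within ±10 % of their steady-hold means — and triggers audio/LED
feedback during a grasp-move-place training task.  The feedback delay is
either zero (immediate feedback, IF) or ramps from 1 s down to 0 s over
30 training trials (intentional-binding feedback, IBF), the manipulation
intended to strengthen the perceived action–consequence coupling (sense
of agency); a no-feedback (NF) session serves as control.  Task
performance is scored from 3-D object trajectories, and the statistics
layer quantifies training effects within and across feedback modes.

The package is aimed at researchers prototyping wearable-sensor feedback
pipelines and at anyone who wants a tested, seeded reference for this
style of within-subject motor-learning analysis.

## What it computes

**Detection.**  Frames are labeled secure (y = 1) when every active
channel c satisfies |v_c − m_c| ≤ 0.1 m_c, where m_c is the hold-window
mean.  A 10-hidden-unit tanh network with logistic output ŷ ∈ [0, 1] is
trained per subject on the pooled 70/15/15 frame split by minimising the
mean binary cross-entropy

CE = −(1/N) Σ [y log ŷ + (1 − y) log(1 − ŷ)]

with Møller's scaled conjugate gradient (no line search; a
Levenberg–Marquardt scaling λ regularises the finite-difference
Hessian-vector curvature estimate) and early stopping on the validation
split.  The analytical baseline declares pinch grasp secure iff the
index and thumb force voltages agree within 10 % of the larger and both
exceed 10 % of full scale — a force-equilibrium test that fails for
tri-pod and whole-hand grips, where thumb opposition is weak.

**Kinematics.**  From each object trajectory, resampled to 100 Hz:
completion time T (time the object moves), pathlength
P = Σ ‖Δx‖ over moving samples, and placement error E (in-plane distance
from the final resting centre to the target).

**Outcomes and statistics.**  Per subject, mode and metric: the
intra-training rate β (OLS slope across the 30 training trials) and the
post-training effect Δ = mean(post) − mean(pre); negative values mean
improvement.  Values are normalized by each subject's pre-training mean
and de-normalized by the group pre-training mean.  The battery mirrors
the study design: repeated-measures ANOVA over trial blocks with
Tukey-HSD post hocs, one-way ANOVA of each outcome across feedback
modes, and one-sample t-tests of each outcome against zero.

## Worked example

```python
from grasplearn import synth, labeling, classifier, feedback, stats

corpus = synth.generate_training_corpus("S01", seed=42)      # 125 trials
dataset = labeling.assemble_dataset(corpus, seed=42)         # 50125 frames
model = classifier.train_ann(dataset, classifier.TrainConfig(seed=42))
report = classifier.evaluate(model, dataset)

sched = feedback.build_schedule("IBF", 30)
study = synth.generate_study(17, seed=1)
rep = stats.build_report(study.to_frame())
```

printed quantities (exact values for these seeds):

```
test error: 0.68 %
pinch TP:   ANN 99.7 % vs analytical 98.4 %
IBF delay ramp: 1.000 s -> 0.000 s (step 34.5 ms)
group pre-training completion time: 1.53 s
IBF intra-training rate: -0.0044 s/trial (t = -3.19, p = 0.0056)
```

Reading: the learned detector misclassifies 0.68 % of held-out frames
and its true-positive rate on secure pinch frames exceeds the analytical
equilibrium rule's; the intentional-binding schedule shrinks the
feedback delay by ~34 ms per trial; and in a default 17-subject
synthetic study the IBF group's completion time falls by ~4.4 ms per
training trial, significantly different from zero.

A command-line surface wraps the same functions:

```bash
grasplearn simulate-corpus --subject S01 --seed 42 --out corpus/
grasplearn label --corpus corpus/ --seed 42 --out dataset.csv
grasplearn train --dataset dataset.csv --seed 42 --out model.json
grasplearn evaluate --model model.json --dataset dataset.csv --out report.json
grasplearn simulate-study --subjects 17 --seed 1 --trajectories --out study/
grasplearn score --study study/ --out metrics.csv
grasplearn analyze --metrics metrics.csv --out report/
```

## Layout

| module | contents |
| --- | --- |
| `grasplearn.synth` | seeded generators: sensor trials, corpora, task trajectories, studies |
| `grasplearn.labeling` | hold statistics, ±10 % band labeling, 70/15/15 assembly |
| `grasplearn.classifier` | SCG-trained network, analytical pinch rule, evaluation report |
| `grasplearn.feedback` | NF/IF/IBF schedules, onset detection, beep/LED events |
| `grasplearn.metrics` | resampling, speed gating, completion time / pathlength / placement error |
| `grasplearn.stats` | normalization, outcomes, RM-ANOVA / ANOVA / Tukey / t-tests |
| `grasplearn.io`, `grasplearn.cli` | CSV/JSON serialization and the `grasplearn` command |

See `docs/methods.md` for the generative model, parameter defaults and
numerical choices.
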