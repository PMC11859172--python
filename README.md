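# mdtwpose

Recognition of high-knee-flexion occupational postures — kneeling,
squatting, floor and chair sitting, stooping, standing and walking —
from lower-limb joint-angle time series, using a weighted
multi-dimensional dynamic time warping (mDTW) distance and
nearest-neighbour matching against a library of movement templates.

Prolonged or repetitive postures in which the knee flexes beyond 120°
are an established occupational risk factor for knee osteoarthritis.
Wearable inertial sensors can estimate sagittal-plane flexion–extension
angles of the ankles, knees and hips all day long, but turning those six
angle channels into *which posture was adopted, when* requires a
classifier that tolerates the temporal and amplitude variability of
human movement. This package implements, end to end, a template-based
approach for that problem, aimed at movement scientists and ergonomists
who want an interpretable (non-black-box) pipeline.

## Method

Each trial is a matrix of six flexion–extension angle channels
(right/left knee, ankle, hip; degrees, 60 Hz). Trials are linearly
resampled to *N* = 101 samples and min–max scaled to [−1, 1] (by
default with one min/max per trial, preserving between-joint amplitude
ratios). For a template channel *t* and a sequence channel *s*, the
local cost matrix is

    D[m, n] = |t_m − s_n|,   m, n = 1 … 101,

and the DTW distance is the minimum accumulated cost over monotone warp
paths built from the moves (+1,0), (0,+1), (+1,+1), constrained to a
Sakoe–Chiba band |m − n| ≤ 50 (a maximum warp of 49.5% of the signal).
The six per-joint distances are fused linearly:

    D_mDTW = 0.26·D_LAnkle + 0.20·D_RAnkle + 0.72·D_LKnee
           + 1.00·D_RKnee + 0.67·D_LHip + 0.76·D_RHip,

and a query is assigned the label of its nearest template (k = 1) under
this metric. The weights, the band half-width and k are selected by
stratified 80/20 holdout plus five-fold cross-validated grid searches,
all implemented in `mdtwpose.model_selection`. Evaluation reports
per-class sensitivity, specificity and balanced accuracy
((sensitivity + specificity)/2), confusion matrices as row percentages,
and grouped-posture summaries (e.g. all kneeling variants as one group).

Because comparable recordings are not openly available, the package
ships a first-class synthetic kinematics generator
(`mdtwpose.simulate`): stand → descend → 5 s hold → ascend → stand
raised-cosine profiles with class-specific peak flexion, per-subject
depth/tempo offsets, per-trial jitter, truncated Gaussian noise,
optional lead-in/out steps and periodic multi-stride gait. Every module
is tested against it.

## Worked example

```python
import numpy as np
from mdtwpose import (WeightVector, generate_cohort, knn_classify)

cohort = generate_cohort(master_seed=1)      # 10 subjects, 3 novel
print(len(cohort.library))                   # 295 templates

query = cohort.novel_queries[0]              # a DK trial, normalized
pred, ranked = knn_classify(query, cohort.library, WeightVector.tuned())
print(pred, query.label)                     # DK DK
print(round(ranked[0].combined, 3))          # 5.575  (nearest template)
```

The nearest-template distance (5.575) is the weighted sum of the six
per-channel DTW distances; identical trials give 0, and larger values
mean less similar kinematics. On this seeded cohort the classifier
reaches 98.4% accuracy on held-out trials of the template-contributing
subjects and 96.3% on entirely novel subjects, while unsegmented
multi-stride walking bouts are predominantly *not* recognized from
single-stride walking templates — the known failure mode of
single-cycle gait templates.

The same pipeline is scriptable from the shell:

```
mdtwpose simulate --out raw --subjects 6 --novel 2 --seed 5
mdtwpose build-templates --in raw/segmented --out library
mdtwpose classify --library library --input raw/build_query/00000_S00_DK.csv
mdtwpose tune --library library --what band --seed 0
```

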