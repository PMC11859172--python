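# Methods

## Problem and model

The package classifies one of twelve occupational postures — dorsiflexed
kneeling (DK), plantarflexed kneeling (PK), flatfoot squatting (FS),
heels-up squatting (HS), child- and adult-chair sitting (CCS, ACS),
arm-supported kneeling (SK), stooping (STP), standing (STD), crossed-leg
sitting (CLS), side sitting (SS) and walking (WLK) — from six
sagittal-plane joint-angle channels (both knees, ankles, hips; degrees,
flexion positive, nominal 60 Hz). Recordings that distinguish single-
from double-arm supported kneeling, or side sitting from side leaning,
are collapsed onto SK and SS respectively, since their lower-limb
kinematics are nearly identical; the relabelling map is total on the 15
raw codes and onto the 12 canonical classes.

Classification is 1-nearest-neighbour in a template space. A template
is a manually (or, for gait, automatically) segmented trial, linearly
resampled to 101 samples and min–max scaled to [−1, 1]. The distance
between a query and a template is a weighted sum of six per-channel
dynamic-time-warping (DTW) distances. DTW absorbs timing differences
(slow vs fast descents) that plain Euclidean distance would punish,
while the Sakoe–Chiba band (half-width 50 samples, i.e. a maximum warp
of 49.5% of the signal) prevents pathological alignments.

### DTW specifics

* Local cost: absolute difference (the Euclidean norm in one
  dimension). Channels are never stacked into a single multivariate
  DTW; fusion happens after the six scalar distances are computed, so
  each joint warps independently.
* The reported distance is the unnormalized accumulated cost along the
  optimal path. Since all compared signals share M = N = 101, dividing
  by M·N (or by path length) cannot change nearest-neighbour rankings;
  both normalizations are available on `WarpResult.normalized()` for
  reporting.
* Two path modes exist. `optimal` solves the full dynamic programme
  C(m,n) = d(m,n) + min(C(m−1,n), C(m,n−1), C(m−1,n−1)) with
  deterministic backtracking (ties prefer diagonal, then vertical, then
  horizontal moves). `greedy` advances from each cell to the admissible
  neighbour with the smallest *local* cost; it is retained as a
  documented alternative because the local-move description is a
  common informal reading of DTW, but it can only ever do worse than
  the dynamic programme (asserted by property test), and `optimal` is
  the default everywhere.
* For unequal lengths the band is taken around the proportional
  diagonal m ≈ n·(M−1)/(N−1); bands narrower than |M − N| are rejected
  with the required minimum reported.
* An exhaustive path-enumeration oracle (`brute_force_dtw`, inputs of
  length ≤ 8) provides an implementation-independent check; the batch
  anti-diagonal vectorized programme used for library classification is
  asserted equal to the single-pair programme to machine precision.

### Scale normalization scope (a deliberate design choice)

The [−1, 1] scaling can be applied per channel (each channel mapped by
its own extrema) or per trial (one min/max across all six channels).
The package default is **per trial**. Per-channel scaling discards all
between-joint amplitude information: a posture is then characterized
only by per-channel waveform *shape*, and since most postures here are
"descend, hold 5 s, ascend" their shapes are nearly identical — on the
synthetic cohort, held-in accuracy collapses to ~72%. Per-trial scaling
preserves the ratios between joint excursions (hip/knee, ankle/knee),
which is exactly where these postures differ, and lifts held-in
accuracy to ~98%. Both modes remain available via
`scale_normalize(..., scope=...)` and the run configuration; the scope
used is recorded in sequence metadata and enforced at validation.

### Weights and model selection

Two named weight vectors ship with the package (ordered L-ankle,
R-ankle, L-knee, R-knee, L-hip, R-hip): `initial` =
(0.25, 0.25, 0.75, 1.00, 0.75, 0.75) and `tuned` =
(0.26, 0.20, 0.72, 1.00, 0.67, 0.76); the right-knee coefficient is
anchored at 1.00 in both (only relative weights matter — scaling all
six by any positive constant provably leaves every prediction
unchanged). The default operating point is band 50, k = 1, tuned
weights.

The model-selection protocol: per class, 80% of templates are randomly
assigned to training (20% withheld; rounding is half-up with a minimum
of one test item, classes with fewer than five templates are rejected);
training templates are dealt round-robin into five stratified folds
(per-class fold sizes differ by at most one); band (0…100 step 10), k
(log-spaced integers between 1 and the training size, deduplicated,
default 20 points) and the weight grid (±0.045 step 0.015 per
non-anchored channel — seven values each — and 0.7…1.0 step 0.05 for
the right knee) are scored by unweighted mean fold accuracy. Ties
select the smallest band, the smallest k, or the weight vector closest
(L1) to the base — the simpler or less-warped model. The full joint
weight grid has 7⁶ = 117 649 combinations and is refused above a
configurable cap (default 20 000) unless explicitly overridden; because
weights enter only the final linear fusion, per-channel distances are
cached once per fold and reused across all weight candidates, which is
what makes the search tractable at all.

### Evaluation

Per class, one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
balanced accuracy (sensitivity+specificity)/2 — all in percent,
full-precision internally. Metrics with zero denominators (a class with
no evaluated items) are reported as NaN/absent, not as 0 or 100.
Display rounding is half-up (one decimal, or whole percent for grouped
summaries); summary spreads use the sample (n−1) standard deviation.
Grouped reports collapse kinematically similar classes
({DK, PK, SK} → kneeling, {FS, HS} → squatting, {ACS, CCS} → chair
sitting, {CLS, SS} → floor sitting; STP, STD, WLK stay singletons);
grouping conserves the grand total and can only convert within-group
confusions into correct predictions, so grouped overall accuracy never
decreases. Chance level is computed as 100/(number of classes) for the
actual class count (8.3% for twelve classes).

## Synthetic kinematics

No comparable public recordings exist, so the generator is first-class,
tested code that defines the study conditions for every pipeline-level
result. Each non-gait trial is, per channel, quiet standing → raised-
cosine descent (1.5 s) → hold at the fully flexed angle (5 s) →
raised-cosine ascent (1.5 s) → quiet standing, at 60 Hz, with optional
half-stride lead-in/lead-out steps for the classes performed from a
step (the seated classes and standing omit them). Gait is a periodic
swing-phase knee bump (stride 1.1 s) with sinusoidal hip motion, the
contralateral leg half a stride out of phase; strides begin and end at
maximum knee extension so trough-based segmentation recovers them.
Walking *movement sequences* are 8-stride bouts with 1 s of standing at
each end, emulating an unsegmented walk recorded from a standing start,
whereas template-source walking trials contain 3 strides each.

Class profiles (peak angles per joint) are fixture parameters chosen to
respect the qualitative posture definitions — high-flexion classes
exceed 120° of right-knee flexion, stooping hinges at the hip with the
knee below 90°, DK/PK/SK differ chiefly in ankle sign, heels-up
squatting has plantarflexed ankles where flatfoot squatting is deeply
dorsiflexed, side/crossed-leg sitting are left-right asymmetric — and,
because per-trial scaling reduces the discriminative information to
between-joint amplitude ratios, the profiles are additionally spaced in
(hip/knee, ankle/knee) ratio space. They are an editable table
(`DEFAULT_PROFILES`), explicitly not measured data.

Variability model: per-subject depth offsets drawn independently per
joint pair (sd 8° knees, 6° hips, 4° ankles) plus a tempo offset
(sd 0.08); per-trial peak jitter (sd 2°) and uniform duration jitter
(±10%); additive measurement noise of sd 1°, truncated at ±3 sd (the
truncation makes flat standing trials provably stay within 3 noise-sd
of baseline). One master seed fans out via counter-based seeding
(master, subject, class, trial, purpose), so any single trial is
regenerable in isolation. Default cohort: 10 subjects of which 3 are
reserved as novel participants, 3 template trials and 3 query trials
per class — 295 templates and 252 held-in queries, enough for the
permutation-null check at n ≥ 200.

What the generator does *not* emulate: transitions between postures,
sensor drift or soft-tissue artefact, non-sagittal degrees of freedom
(hip internal/external rotation, which in real data separates side
sitting from kneeling), and realistic within-hold sway. Passing
pipeline tests therefore demonstrate the correctness and internal
consistency of the method at its operating point, and qualitative
phenomena (novel subjects are harder; single-stride templates fail on
multi-stride walks), not field accuracy on real recordings.

## Numerical choices and degenerate inputs

* Interpolation grid: uniform in normalized time [0, 1], endpoints
  inclusive (101 points ⇒ step 0.01); endpoints are copied exactly.
* Constant channels/trials scale-normalize to 0 (midpoint), avoiding
  division by zero; a flat channel carries no shape information.
* Gait boundaries: `scipy.signal.find_peaks` troughs on the negated
  knee flexion channel, minimum prominence 5°, minimum separation
  0.4 s; the trial's start/end count as boundaries when the knee is
  within the prominence threshold of the global minimum there; spans
  without a prominent flexion peak are dropped. Fewer than two
  boundaries ⇒ empty result with a warning.
* Exact distance ties in classification resolve by stable library
  order (the order is serialized with the library); k > 1 majority
  ties resolve by the smaller mean distance among tied classes, then
  canonical class order.
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; identical seeds give bit-identical trials, splits and
  reports.

## Problem sizes

Default test and reproduction runs use the 10-subject cohort above
(295 templates, 252 + 108 + 360 queries), a 1000-pair oracle check, and
reduced weight grids in tests; these sizes were chosen so the whole
suite completes in minutes on a single core while every check retains
comfortable statistical margins.

## Known limitations

* The greedy path mode is a documented curiosity, not a recommended
  setting.
* Balanced accuracy inflates for rarely predicted classes in
  multi-class settings (TN dominates); grouped summaries mitigate but
  do not remove this.
* The published tuned left-hip weight (0.67) lies outside the stated
  ±0.045 search range around 0.75; the vector is taken at face value as
  the canonical default rather than asserted to be reachable from the
  default grid.
* With per-trial scaling, a posture's absolute depth is still not
  observable — only joint ratios are; two postures differing *only* by
  uniform depth across all joints are indistinguishable by design.
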