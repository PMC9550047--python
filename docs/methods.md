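# Methods

## Problem setting

Semantic segmentation of anisotropic 3-D MRI-like volumes into four
anatomical classes around the rotator cuff — muscle, humerus, cuff tendon,
humeral-head cartilage — with a specific failure mode: an *unlabelled*
structure of tendon-like intensity (the biceps long head analogue) that a
plain multi-class model systematically predicts as cuff tendon.  The package
implements the two-stage *secondary labelling* strategy for suppressing such
false positives:

1. **Harvest.** Split the training cohort into k folds.  For each fold,
   train a segmentation model on the other folds and predict the held-out
   cases, so every case is predicted by a model that never saw it.  A
   case's harvested mask is the set of voxels predicted as the target class
   (tendon) where the ground truth is *background*.  Voxels where the truth
   carries another foreground class are never harvested: the original
   labels are preserved bit-exactly.
2. **Relabel.** The harvested voxels become a new auxiliary class, turning
   the 5-class dataset (4 structures + background) into a 6-class one.
3. **Retrain and discard.** A fresh model is trained on the relabelled
   dataset.  At inference the auxiliary class competes in the softmax and
   argmax like any other; voxels it wins are then remapped to background.
   The auxiliary class can therefore never appear in an output map.  The
   discard is a post-argmax remap, not a renormalization over the retained
   classes — renormalizing would let the tendon reclaim exactly the voxels
   the auxiliary class was invented to absorb.

## Evaluation

Per class and case, voxel tallies TP/FP/FN give

    DSC = 2TP / (2TP + FP + FN),    IoU = TP / (TP + FP + FN),

algebraically linked by IoU = DSC/(2 − DSC).  A class absent from both maps
scores 1.0 (configurable): a correctly absent class should not poison a case
mean.  Cohort summaries report mean ± sample (n−1) SD per class; the
"overall" row is the mean over the per-class means.  Baseline-vs-refined
comparison uses a two-sided paired t-test on per-case metrics; tear-size
subgroup comparison uses classical one-way ANOVA.  Both delegate to
scipy.stats after degenerate-input checks (zero-variance differences,
zero within-group variance) that scipy would silently turn into NaNs.
Significance is reported at p < 0.05; no multiple-testing correction is
applied.

## Loss

The training loss combines weighted cross-entropy with a soft-Dice term:

    L = −Σ_v w(y_v) log p(y_v | v)  +  1 − mean_c (2|y_c ∩ ŷ_c| + ε) / (|y_c| + |ŷ_c| + ε)

with ε (default 1e-5) guarding empty-empty classes, whose Dice ratio is then
exactly 1 and contribution exactly 0.  The Dice mean runs over foreground
classes only; including the background would swamp the term.  The public
`combined_loss` uses the sum form of the cross-entropy (so a uniform binary
prediction over N voxels yields exactly N·ln 2); the training loop divides
the CE term by the voxel count so usable learning rates are independent of
patch size.

Two loss details are deliberate design choices:

- **Auxiliary class is CE-only.**  In refined training the auxiliary
  pseudo-class is excluded from the Dice average (`dice_classes`).  The
  auxiliary class and the tendon are identical in appearance by
  construction, so a Dice reward on the auxiliary class makes the
  tendon/auxiliary decision boundary unstable at small scale — we observed
  seed-dependent collapse of the entire tendon class into the (discarded)
  auxiliary class.  Cross-entropy supervision at the harvested voxels is
  sufficient for the mechanism and keeps the tendon's own Dice incentive
  intact.
- **Class weights default to 1; the auxiliary class is upweighted.**  The
  weighting of the cross-entropy is exposed (`class_weights`) and defaults
  to uniform for the anatomical classes.  In refined training the auxiliary
  class receives weight 4: it is roughly an order of magnitude rarer than
  the anatomical classes, and without upweighting it rarely wins the argmax
  at inference, so the discard step has nothing to discard and the
  false-positive reduction does not materialize.  This is the role class
  weighting plays in this loss design.

## Network and training

A conventional U-Net, configurable between 2-D (per-slice, full-resolution
input) and 3-D (patch-based): `depth` encoder stages of two
(conv → instance-norm → leaky-ReLU) blocks with channel doubling and max
pooling, a symmetric decoder with nearest-neighbour upsampling and skip
concatenation, and a 1×1 convolution head.  The layer stack, including all
backward passes, is implemented directly on numpy (module `cuffseg._nn`);
gradient correctness is established by finite-difference checks in the test
suite (exact to ~1e-6 in float64).

Optimization is SGD with momentum 0.9, batch size and epoch length
configurable, and early stopping on a tuning loss computed on a frozen set
of tuning-case patches; the parameters of the best tuning epoch are
returned.  The learning rate is fixed by default with optional polynomial
decay (`lr_decay_power`); the desk-scale experiments use peak 0.2 with
power-0.9 decay, which proved markedly more stable for the small networks
than a fixed rate.  Patches are sampled with a configurable foreground bias
and augmented by in-plane rotation and scaling (applied identically to image
and label, nearest-neighbour for labels) and brightness/contrast/gamma
(image only).  Rotations are in-plane only: the strong slice-axis anisotropy
(2.5 mm vs 0.29 mm) makes through-plane rotation destructive.

Whole-volume inference is sliding-window with 50% overlap; per-class
probabilities are averaged over windows and renormalized; argmax ties break
toward the lowest class index.  Volumes smaller than the patch are
zero-padded, predicted and cropped.

## Synthetic phantom

Each case is a (slice, row, col) grid — default 16×64×64 at
2.5×0.29×0.29 mm, the scaled-down analogue of a full-resolution anisotropic
acquisition — containing:

- **Humerus**: sphere (head) plus inferior cylinder (shaft).
- **Cartilage**: thin shell (0.22 r_head) over the upper head.
- **Cuff tendon**: curved sheet — a radial shell band capping the head over
  a ~70° polar cap about a per-case tilted "up" axis.
- **Muscle**: medial prism abutting the tendon's medial edge.
- **Confuser** (unlabelled): a strip of the *same* radial shell on the far
  (bicipital-groove) side of the head, over a seeded-random azimuth window,
  kept at least `confuser_gap_mm` (default 1.5 mm) from the tendon by a
  distance-transform erosion.  Its intensity equals the tendon's, so its
  local appearance — a curved tendon-intensity band hugging the humeral
  head — is indistinguishable from cuff tendon; only its position differs.
  An earlier design (an isolated thin tube away from all structures) turned
  out to be too easy: baseline models produced *no* false positives on it,
  so it could not exercise the mechanism under study.
- **Tear**: per-case category (intact / partial / small / medium / large /
  massive) removes a nested azimuthal window of the tendon sheet of
  fractional width 0 / 0.1 / 0.2 / 0.35 / 0.55 / 0.8.  The nesting makes the
  tendon volume monotone non-increasing in severity at fixed seed.  The
  schedule is a stand-in: the clinical grading has no published quantitative
  geometry.

Per-case jitter (head centre ±4% of the field of view, radius ±8%, cap-axis
tilt ±12°, random tear and confuser azimuths) keeps cohorts from being
clones of one geometry.  The image is the sum of class indicators times
their mean intensities, times a smooth multiplicative bias field (product of
cosines, amplitude 0.15), plus additive Gaussian noise (SD 0.05 on an
intensity range of ~0.85).  Intensities are chosen so classes are separable
by intensity except tendon vs confuser, which are identical.

What the phantom does *not* emulate: realistic MRI texture and partial
volume effects, Rician noise, scanner/protocol variability, anatomical shape
realism, and annotation noise.  Passing the end-to-end tests therefore
demonstrates that the *mechanism* (cross-validated harvesting, relabelling,
discard) behaves as designed when an intensity-confusable unlabelled
structure is present — not that any particular clinical accuracy would be
attained on real data.

## Desk-scale study sizes

The end-to-end experiment (`cuffseg.experiment`) uses 20-case cohorts,
split 60/20/20 (largest-remainder rounding, ties toward training — the same
rule that produces a 34/11/11 split of a 56-case cohort), k=2 folds for
harvesting, a 3-D U-Net with base width 6 and depth 2 on 8×32×32 patches,
batch 4, epochs of 8 steps.  Epoch budgets differ by stage on purpose:
the baseline gets 40 epochs; the fold harvesters only 25 — lightly trained
harvesters over-predict the target class, which yields broad, consistent
false-positive coverage of the confuser and hence consistent auxiliary
supervision; the refined model gets 60, since it solves the hardest
discrimination (tendon vs an appearance-identical auxiliary class).  These
sizes were chosen so a full three-seed replication runs on a single CPU in
minutes; the pipeline is size-agnostic and accepts full 512×512 in-plane
grids and the conventional 16×320×320 patches through the same
configuration surface.

## Numerical choices and degenerate inputs

- Intensity normalization: clip to the [0.5, 99.5] percentile band, then
  z-score over the volume ("histogram-based" normalization is
  under-specified in the field; this is the closest widely understood
  reading).  A constant volume normalizes to all zeros with a warning.
- Resampling: output shape per axis is round(shape × spacing / target);
  linear interpolation for intensities, nearest-neighbour for labels (never
  invents a class).
- Argmax ties break toward the lowest class index (determinism).
- Fold assignment and dataset splits are seeded permutations; fold sizes
  differ by at most one.
- Empty-empty metric convention: DSC = IoU = 1.0, configurable.
- All stochastic stages consume explicit integer seeds; per-fold models use
  seed = base + fold index; reruns are bit-identical on CPU.

## Known limitations

- The numpy network trains small models only; no GPU path, no deep
  supervision, no 2D+3D ensembling, no automatic topology configuration.
- Mesh export (marching cubes at the 0.5 iso-level, vertices in mm) is a
  visualization convenience, off the critical path.
- The secondary-labelling procedure is applied once, to a single target
  class; iterating it, or harvesting false negatives, is out of scope.
- Orientation metadata beyond voxel spacing is ignored.
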