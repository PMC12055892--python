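# Methods

## The simplified-label model

Semantic segmentation ground truth is usually authored at full class
granularity ("strong" labels), which in surgical imaging requires annotators
who can tell, say, a liver from a gallbladder or an L-hook from a grasper.
`simlabel` implements the alternative of *semantically weak* labels: classes
are partitioned into a small number of visually obvious groups (tissue,
organ, tool, background), and an annotator without domain expertise labels
at the group level.

Formally, a grouping of `n` classes into `m` groups is realised by a binary
`m × n` matrix **M** with

```
M[i, j] = 1  iff class j belongs to group i,
```

so each column sums to exactly 1. For any nonnegative class vector **y**,
the group vector **y′ = M y** has the same element-wise sum, stays
nonnegative, and is 1-hot whenever **y** is 1-hot — so group-level labels
remain valid targets for any classification loss. A simplified training
sample is the triplet {**x**, **y′**, **M**}; training minimises

```
Loss = L(M ŷ, y′)
```

where **ŷ** is the model's per-pixel class-probability map and the
projection is applied pixel-wise. With **M = I** this reduces *exactly* to
ordinary supervised training: the implementation guarantees bit-for-bit
equality (projecting through the identity multiplies by 1.0 and adds exact
zeros, both exact in IEEE arithmetic), and the test suite asserts it both at
the loss level and over an entire training run.

## Loss

The training objective is the Combo loss

```
L = α · mCE − (1 − α) · DSC
```

with `mCE` a modified cross-entropy weighting false negatives against false
positives by `β`, summed over classes and averaged over pixels, and `DSC`
the soft Dice coefficient with smoothing `ε`, computed per class with
counts pooled over the batch and averaged over classes. Defaults:
`α = β = 0.5`, `ε = 1e-6`, probabilities clamped to `[1e-7, 1 − 1e-7]`
before logarithms. The α/β mix is a neutral default, exposed in
`LossConfig`.

## Training strategies

Strong targets have `n` channels and simplified targets `m`, so the two
label kinds cannot share a minibatch; scheduling happens at the *epoch*
level. All three strategies span 25 epochs with Adam, batch size 8, and a
learning-rate drop from 5e-4 to 1.25e-4 for the final 5 strong epochs:

| strategy         | stage 1                 | stage 2          | stage 3          |
|------------------|-------------------------|------------------|------------------|
| strong_first     | 10 strong               | 10 simplified    | 5 strong, low lr |
| simplified_first | 10 simplified           | 10 strong        | 5 strong, low lr |
| mixed            | 10 × (strong, simplified) pairs     || 5 strong, low lr |

`mixed` is the default everywhere (it is the best-performing strategy in
this framework's setting). Within a mixed pair the strong epoch comes
first; a flag reverses the order. Shuffling is epoch-keyed by
`(seed, epoch index)` so runs are exactly reproducible. An empty simplified
pool degrades to strong-only training with a warning (the all-medical
baseline reuses the same code path); an empty strong pool is an error,
since meaningful training requires at least some class-level supervision.

## Mean Dice

Per class `c`, `Dice_c = 2|P_c ∩ T_c| / (|P_c| + |T_c|)` with the counts
pooled over the whole evaluation set before dividing (micro per class),
then averaged over classes including background (macro). A class absent
from both prediction and target over the entire set scores 1 by convention
and is flagged. Per-image averaging is available behind a flag. These
aggregation choices are documented defaults; other conventions (per-image
averaging, scoring empty classes as 0) exist in the field.

## Reference model

A seeded 3-level encoder-decoder with skip connections (one 3×3
convolution + ReLU per level, widths 16/32/64, nearest-neighbor upsampling,
~70k parameters), implemented on a compact numpy reverse-mode autodiff
engine (`simlabel.nn`). The framework's claims are model-independent, so
the backbone is deliberately small enough for CPU experiments; any model
exposing per-pixel class scores at input resolution can be plugged in via
the `SegmentationModel` contract. Input images are normalised to [-1, 1];
initialisation is He-normal from a seeded generator; gradients are verified
against central differences in the test suite.

## Synthetic study conditions

Every experiment runs on generated scenes, so the whole pipeline is testable
without downloads. The default primary dataset emulates the statistical
structure the method assumes:

- **Four visual families** with well-separated base colors (≳60 grey
  levels): tissue-like blobs (random-walk-smoothed polygons), organ-like
  ellipses, tool-like capsules that always enter from the image border
  (laparoscopic geometry), and a dark background filling residual pixels.
  Group membership is therefore decidable from local appearance alone — a
  per-pixel nearest-base-color classifier exceeds 90% family accuracy — the
  analogue of a layperson recognising "that is a tool".
- **Expertise-bound class identity.** Each family contains two classes
  whose colors differ by only ±9 per channel, against per-pixel noise σ=8
  and a per-scene lighting shift σ=10 (one draw per channel shared by the
  scene, emulating illumination changes between frames). Because the
  lighting shift is collinear with the sibling-class color discriminant,
  a class boundary learned from few scenes does not transfer; resolving
  sibling identity takes many class-labeled scenes, while group identity is
  learnable from any scene. The second class of each family is also rarer
  (frequency weight 0.4–0.5 vs 1.0), so strong-label *quantity* governs how
  well it is learned.
- **Scale.** 64×64 RGB scenes; the team experiment uses 200 scenes in 5
  folds of 40 (fold 0 held out, the team labels folds 1–4), one CV split
  per seed, seeds 1–5; the multi-dataset experiment uses 100 primary scenes
  with all four training folds strong plus 40 scenes of a disjoint-class
  secondary dataset. These sizes are the package's desk-scale defaults:
  large enough that the 25-epoch schedule brings each arm near its
  plateau — so arms differ by the information in their labels rather than
  by optimizer step counts — while a full trend experiment still runs on an
  ordinary CPU.

The secondary dataset emulates a porcine robotic-surgery dataset with a
class set disjoint from the primary one (kidney-like blobs, an intestine
class, instrument capsules, an "other tissue" backdrop). Its field of view
is tissue everywhere except instruments — there is no dark void — so after
mapping both datasets into shared groups ("biological", "non_biological",
and the primary background group, which receives no secondary class) its
supervision is consistent with the primary dataset's. The choice of where
secondary background tissue maps is explicit in the shared-group spec; an
earlier draft that gave the secondary backdrop a dark, background-like
color while mapping it to "biological" produced contradictory supervision
and made joint training strictly worse — the generator now avoids that
known failure mode, and users composing their own shared specs should too.

What the generator does **not** emulate: texture, specularity, smoke,
motion blur, deformation, occlusion boundaries with soft edges, annotator
error (annotators are perfect at their granularity), and temporal
correlation between frames. Passing trend tests therefore show that the
*machinery* behaves as designed under the assumed statistical structure,
not that a particular Dice level would be reached on real surgical video.

## Annotator-team simulation

The training folds are each "authored" by one simulated annotator: medical
annotators contribute the fold's strong labels unchanged; non-medical
annotators contribute the fold's labels pushed through **M** (perfect
group-level annotation). Teams must contain at least one medical annotator.
Fold roles are assigned in fold order with an optional rotation parameter;
the cross-validation harness trains one model per (repeat, held-out fold)
with seeds derived as `seed·10⁴ + repeat·10² + fold` (kept below 2³¹).
Compositions are compared with a two-tailed paired Student's t test on the
matched Dice samples (degenerate all-equal inputs are rejected).

## Numerical choices

- float32 throughout the network; float64 in the label algebra.
- Probability-sum checks: 1e-6 on inputs; conservation asserted to 1e-9 in
  tests.
- Dice smoothing ε=1e-6; log clamp 1e-7.
- Maxpool ties break toward the first element (argmax convention);
  upsampling is nearest-neighbor.
- Mask resizing is always nearest-neighbor; image resizing bilinear.
- Group order is the order groups first appear in a config, never
  alphabetical, so matrices are reproducible across runs.
- Empty groups are rejected unless explicitly allowed (`allow_empty_groups`),
  which the multi-dataset workflow needs for the primary background group.

## When group-level supervision backfires

Per-class measurements on the synthetic task reproduce a known failure mode
of semantically weak labels: classes that are *hard to learn at class level*
(here, the rare sibling classes; in surgical data, a class like the
gastrointestinal tract) lose accuracy when large amounts of group-only
supervision are added, because the group loss constrains only the sum of
within-group probabilities and training drifts toward the dominant sibling.
Tool-like classes, by contrast, hold or improve — group supervision carries
most of their signal. On the default synthetic pair this effect makes joint
training with the secondary dataset roughly Dice-neutral to slightly
negative: the default primary dataset deliberately contains *three*
expertise-bound rare classes (that structure is what makes the annotator-
team comparisons meaningful), and their degradation under group-only
supervision is not offset by gains on the already-saturated common classes.
Joint training should therefore be expected to pay off when the baseline
model still has headroom on robust, group-alignable classes, and to be
counterproductive when several difficult classes dominate the evaluation —
which is worth checking per dataset before adopting it.

## Known limitations

- The reference model is far below the capacity of the segmentation
  backbones used in large-scale studies; absolute Dice values on the
  synthetic task are not comparable to published values on real datasets.
- Trend experiments use one CV split per seed rather than the full
  repeated-CV layout (which remains expressible through
  `crossval_experiment(splits=..., repeats=...)`).
- Annotator error is deliberately out of scope: simplified labels are
  derived from ground truth, so non-medical annotators are simulated as
  perfect at group granularity.
- Only single-level groupings (plus one composition step) are supported;
  no overlapping or soft group memberships.
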