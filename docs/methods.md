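# Methods

## Weighting model

A classifier's skill is summarised by the binary correctness indicator of
its hard predictions (argmax of each probability row; ties resolve to the
lowest class index for reproducibility). With empirical accuracy *a*, the
indicator's entropy is the binary entropy H(a) in bits, and the classifier's
information gain is

    IG = alpha * max(0, H0 - H(a)),

with H0 the reference entropy before conditioning on the classifier. H0
defaults to 1 bit — the maximal-uncertainty state of a two-outcome
variable — which reads "before consulting this classifier we know nothing
about whether it is right". Weights are gains normalised to sum to one,
and fusion is the weighted average of the probability matrices.

Assumptions and consequences:

- **Binary, not multiclass, entropy.** Skill is compressed to
  right/wrong; the model is deliberately blind to *which* wrong class was
  predicted. No multiclass entropy variant is offered.
- **The entropy gap is symmetric about a = 1/2.** A 10 %-accurate
  classifier scores like a 90 %-accurate one. Below 0.5 the score no
  longer reflects skill, so accuracies under 0.5 raise an `IGPAWarning`
  rather than being silently clamped or re-weighted; callers operating in
  that regime should inspect their classifier bank.
- **Zero total gain** (every classifier exactly at chance) leaves the
  weight ratio undefined; the implementation falls back to uniform weights
  with a warning.
- **alpha enters multiplicatively and cancels** in the normalisation, so
  in the default mode the level index has no numerical effect — the
  faithful rendering of the formula as stated. Because the level is
  nonetheless described as amplifying the dominance of stronger models as
  ensembles stack, an explicit opt-in `mode="exponent"` computes
  `(H0 - H(a)) ** alpha`, which does amplify: for alpha2 > alpha1 >= 1 the
  best/worst weight ratio is non-decreasing. The mode is recorded in every
  report; the default stays faithful.

## Multi-level trees

Leaves (level 0) are classifier outputs; an internal node's level is one
more than its highest internal child, and its alpha defaults to its level.
Each node optionally keeps its top-k most accurate children (accuracy ties
break toward the lexicographically smaller source id), then fuses them with
IGPA at its alpha. The reference topology is three levels: nine backbone
nodes (DN121, DN169, DN201, MNv1, MNv2, MNv3L, Iv3, IRv2, X) each over four
attention-head variants (CCNN, CACNN, SEACNN, SACNN); three family nodes
DN = {DN121, DN169, DN201}, MN = {MNv1, MNv2, MNv3L}, IX = {Iv3, IRv2, X};
one root. That is 36 leaves and 13 internal nodes. The "best3" variant
applies top-3 selection at every node (a no-op at the three-child family
and root nodes, set uniformly for symmetry). The MobileNet backbone is
labelled MNv1 so its node id stays distinct from the family node MN.

**Weighting labels.** Which partition feeds the correctness computation is
the caller's choice. Weighting on the evaluation set leaks information and
inflates results, so the CLI demands an explicit `--allow-leak` when the
same file serves both roles, and the library supports leak-free weighting
via `weighting_rows`: correctness (and top-k ranking) is computed on a row
subset — typically the validation partition — while fusion covers every
row. The acceptance pipeline uses this mode.

## Evaluation metrics

All rates derive from the confusion matrix (rows = true class) through the
one-vs-rest decomposition. Precision, recall and F1 aggregate
support-weighted; the weighted recall is then algebraically identical to
accuracy (sum of per-class TP over total), which is why recall always
equals accuracy in the reports. Specificity aggregates macro (unweighted):
a support-weighted true-negative rate would be dominated by the majority
class and sit near the accuracy, whereas the macro average exposes
performance on minority classes. Per-class values with a zero denominator
are reported as 0 with a warning rather than dropped. ROC-AUC is
one-vs-rest per class (scikit-learn's rank-based implementation, equal to
the pairwise positive-over-negative comparison count with ties at 1/2,
which the test suite verifies to 1e-9) and macro-averaged over the classes
for which it is defined. Percentages are rounded half-even to two decimals.

## Attention operators

Inference-only forward passes with caller-supplied weights:

- **Channel attention** builds a per-channel descriptor — the channel means
  and, by default, their standard deviations (`descriptor_mode="mean_std"`,
  descriptor length 2C; mean-only is available) — and gates channels with
  `sigmoid(W2 @ relu(W1 @ d))`. Gates lie in (0, 1), so the output norm
  never exceeds the input norm. The hidden width is free; the helper
  default is C/8 with floor 1.
- **Squeeze-and-excitation** pools each channel to its global average and
  scales by `relu(W2 @ sigmoid(W1 @ z))`. This activation order (outer
  ReLU, inner sigmoid) inverts the conventional squeeze-excitation block —
  it is implemented exactly as specified, and has the visible consequence
  that zero weight matrices annihilate the output instead of halving it.
  No intent is guessed beyond the stated form.
- **Soft attention** is a max-shifted softmax over scalar scores; invariant
  to adding a constant, safe against overflow, and rejecting non-finite
  scores.

## Synthetic data generator

The simulator emulates the experiment the ensemble machinery targets: a
bank of image classifiers over seven dermoscopy classes with the HAM10000
imbalance (empirical proportions of the 10015-image dataset; NV ≈ 66.9 %).
Truth labels are drawn from that prior. Per classifier and sample,
correctness is decided by a Bernoulli draw at the classifier's target
accuracy — either independent, or (with probability `correlation`) driven
by a per-sample shared uniform "difficulty" draw so that classifiers err on
the same hard samples. With `correlation=1` and equal accuracies the
correctness vectors coincide exactly. A wrong prediction picks a class
uniformly among the others (an optional confusion-bias matrix hook exists
for harder fixtures, since no confusion structure is prescribed). The
probability row is a flat Dirichlet noise vector plus `concentration`
(default 8) extra mass on the predicted class, renormalised; for any
concentration above 1 the row's argmax is guaranteed to be the intended
prediction, so the designed correctness draw is realised exactly and the
empirical accuracy is binomial around the target.

What the generator does **not** emulate: class-dependent confusion
structure (melanoma/nevus confusability), probability calibration patterns
of real softmax heads, augmentation effects, or inter-class difficulty
gradients. Passing tests therefore demonstrate the correctness of the
weighting/fusion arithmetic and the ordering behaviour of the methods under
controlled skill differences — not that IGPA's accuracy advantage on real
dermoscopy data is reproduced here.

Manifests assign each lesion a class and distribute images over lesions
(every lesion gets at least one image; surplus images land uniformly, so
some lesions carry several). The grouped splitter shuffles lesion ids by
seed and greedily assigns whole lesions to fill the test quota, then the
validation quota (image-count quotas, `round(n * fraction)`), remainder to
train. Exact 70/15/15 sizes are guaranteed when lesions are unique and the
counts divide exactly; with multi-image lesions the quotas are met as
closely as whole-lesion assignment allows. No lesion ever spans partitions.

## Numerical choices

- Entropy in bits (log base 2); `0 log 0 := 0`; results clipped to [0, 1]
  against rounding at the boundaries.
- Row-stochasticity tolerance 1e-6 on input matrices, weight-sum tolerance
  1e-9; serialized probabilities carry 9 significant digits, making CSV
  round-trips lossless at 1e-12.
- Argmax ties: lowest class index. Majority-vote ties: largest summed
  probability over the tied classes, then lowest class index. Accuracy
  ties in ranking/selection: lexicographically smaller source id, then
  input position. All deterministic.
- Softmax with max-shift; Dirichlet sampling via numpy's `default_rng`,
  fully determined by the configured seed.

## Problem sizes

The test suite and the acceptance pipeline run on simulated banks of up to
36 classifiers at 1000–5000 samples — large enough that binomial noise on
an accuracy is ~0.5 % and skill orderings are stable, small enough that
the whole suite runs in seconds on one core. The acceptance pipeline uses
3000 samples (450 in each 15 % partition) with leaf accuracies drawn in
0.85–0.95 and error correlation 0.9, chosen because co-trained deep
classifiers concentrate their errors on shared hard cases; with
near-independent errors a 36-classifier fusion would be almost perfect and
the comparison between fusion rules would be vacuous.

## Known limitations

- The weighting uses only aggregate accuracy; two classifiers with equal
  accuracy but complementary error sets receive equal weights, although
  their combination value differs.
- Fixed-weight baselines require exactly the preset's classifier count;
  arbitrary weight sequences are accepted for other counts.
- The exponent alpha mode changes weights but the tree still recomputes
  correctness from fused outputs at each level, so dominance amplification
  interacts with selection in ways the faithful mode avoids; reports
  always record the mode.
- No probability calibration (e.g. temperature scaling) and no trained
  meta-learner stacking; fusion is strictly convex averaging.
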