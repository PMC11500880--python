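# igpa — information-gain proportioned averaging for classifier ensembles

`igpa` fuses the class-probability outputs of multiple classifiers by
weighting each one in proportion to the *information gain* of its
correct/incorrect indicator, and stacks that rule level by level into a
multi-level ensemble tree. It was built for multi-CNN dermoscopy skin-lesion
classification (seven HAM10000-style classes, heavily nevus-dominated), but
the machinery is generic: anything that emits row-stochastic probability
matrices can be fused.

It is aimed at people who already have a bank of trained classifiers — the
package never trains models. It ships:

- the IGPA weighting and fusion rule, and its multi-level variant (ML-IGPA)
  with a built-in 36-classifier reference topology (9 backbones × 4
  attention heads → DenseNet / MobileNet / Inception-Xception families →
  root);
- the classical baselines it is compared against: softmax averaging,
  majority voting, and fixed-profile weighted averaging (30/26/24/20 % for
  four classifiers, 35/35/30 % for three), plus top-k classifier selection;
- multiclass evaluation (confusion matrix, accuracy, support-weighted
  precision/recall/F1, macro specificity, one-vs-rest ROC-AUC);
- forward passes of the three attention operators (channel attention,
  squeeze-and-excitation, soft attention) on caller-supplied weights;
- a synthetic prediction simulator with controllable accuracy and error
  correlation, and lesion-grouped 70/15/15 splitting that never lets two
  images of one lesion straddle a partition;
- a CLI (`igpa simulate | split | ensemble | tree | metrics | compare`).

## The method

Each classifier *i* predicts a class per sample; comparing against true
labels gives a binary correctness indicator with empirical accuracy
*a<sub>i</sub>*. Its information gain is the entropy reduction relative to a
reference state of maximal uncertainty,

> IG<sub>i</sub> = α · max(0, H₀ − H(a<sub>i</sub>)),  H(a) = −a log₂ a − (1−a) log₂(1−a),  H₀ = 1 bit,

where α is the ensemble level. Weights are the normalised gains,
w<sub>i</sub> = IG<sub>i</sub> / Σ<sub>j</sub> IG<sub>j</sub>, and the fused
prediction for sample *j* is E<sub>j</sub> = Σ<sub>i</sub> w<sub>i</sub>
p<sub>ij</sub>. Because the multiplicative α cancels in the normalisation,
the default ("faithful") mode yields level-independent weights; an opt-in
exponent mode, (H₀ − H(a))<sup>α</sup>, makes higher levels amplify the
dominance of stronger classifiers. ML-IGPA applies the rule bottom-up
through a tree: heads fuse into backbones (α = 1), backbones into families
(α = 2), families into the final prediction (α = 3), optionally keeping
only the top-3 children at each node.

## Worked example

Simulate four classifiers (target accuracies 0.95/0.90/0.88/0.85, errors
85 % correlated, as co-trained CNNs behave) and compare fusion methods:

```sh
igpa simulate --n-samples 1000 --accuracies 0.95,0.90,0.88,0.85 \
     --correlation 0.85 --seed 42 --out-dir sim
igpa compare sim/clf00.csv sim/clf01.csv sim/clf02.csv sim/clf03.csv \
     --weight-labels sim/labels.csv --eval-labels sim/labels.csv \
     --allow-leak --out compare.json
```

prints

```
method      accuracy   precision      recall          f1 specificity
igpa           94.30       95.60       94.30       94.66       99.06
sa             92.70       94.75       92.70       93.32       98.80
mv             92.70       94.75       92.70       93.32       98.80
wa4            94.10       95.46       94.10       94.48       99.03
```

IGPA assigns the 0.95-accurate classifier weight 0.341 (against 0.185 for
the weakest; the full vector is in `compare.json`) and beats the unweighted
mean and majority vote by 1.6 accuracy points on this fixture — weighting
by skill matters exactly when classifiers share their errors. Recall equals
accuracy because recall is support-weighted. `--allow-leak` is required
here because the same labels weight and evaluate; in a real pipeline you
would pass validation labels to `--weight-labels` and held-out test labels
to `--eval-labels`.

The library surface mirrors the CLI, e.g.:

```python
from igpa import igpa_ensemble, reference_topology, run_tree
fused, weights = igpa_ensemble(preds, val_labels)          # one level
fused, report = run_tree(reference_topology("best3"),      # three levels
                         store, val_labels)
```

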