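# haikal

Weak-supervision labeling and training-set augmentation for
protein–protein docking model classification.

## The problem

Protein–protein docking samples 10³–10⁵ candidate 3D poses ("decoys" or
docking models) per complex, of which only a handful are correct — close
enough to the experimental structure to be called Acceptable, Medium or
High quality under the CAPRI criteria. Training a machine-learning
classifier to separate correct from incorrect decoys is starved for
labeled data: reliable labels require an experimental structure to
compare against, and the labeled benchmarks cover only a couple of
hundred complexes.

`haikal` implements a weak-supervision pipeline that turns the scoring
functions every docking study already computes (statistical potentials,
energy terms, consensus scores — one numeric column per decoy) into
*labeling functions* (LFs) and uses them to mass-label decoys of
complexes that have **no** experimental structure, producing a large
"silver" training set that augments the small gold-labeled "core" set.

## The method

For each candidate scoring function *f* (screened by ROC AUC), two
thresholds are searched over the observed values so that the resulting
rule votes only where it is reliable and abstains in between:

    CorrectThreshold   = argmax  R_corr / R_Fp   subject to  Tp > 10% of correct
    IncorrectThreshold = argmax  R_inc  / R_Fn   subject to  Tn > 10% of incorrect

with `R_corr = Tp/(Tp+Fn)`, `R_Fp = Fp/(Fp+Tp)`, `R_inc = Tn/(Tn+Fp)`,
`R_Fn = Fn/(Fn+Tp)`. Each selected LF votes +1 (correct), −1
(incorrect) or 0 (abstain) per decoy. A generative label model — a
two-class conditionally independent Dawid–Skene model with abstention
as an explicit outcome, fit by EM from the votes alone — estimates each
LF's class-conditional vote behaviour and aggregates the votes into a
posterior probability of correctness per decoy.

Downstream, the package builds the field's standard training sets
(per-target balanced sets by random undersampling with a 600-correct
cap; unbalanced "3K" sets of 3000 decoys per target), appends the class
probabilities of core-trained classifiers as extra features, trains
perceptron / dense-net / random-forest classifiers on core vs augmented
data, and evaluates with the eight confusion metrics (per-class
precision, recall, F1, accuracy, MCC) and the per-target top-*N*
success rate.

A synthetic-data generator with known ground truth (class-conditional
Gaussian scoring functions of tunable AUC, shared-confounder feature
correlation, per-target score shifts and prevalences, Poisson clash
counts) makes every stage testable without the multi-gigabyte real
decoy corpora.

## Worked example

```python
import numpy as np
from haikal import SyntheticConfig, generate
from haikal.dataset_builder import build_balanced
from haikal.pipeline import run_weak_supervision

table = generate(SyntheticConfig(n_targets=10, decoys_per_target=300,
                                 prevalence=(0.1, 0.4), seed=7))
balanced, report = build_balanced(table, seed=0)
print(f"balanced training set: {len(balanced)} decoys "
      f"({report['n_correct_kept'].sum()} correct)")

ws = run_weak_supervision(balanced, auc_min=0.6, top_fraction=1.0, k=8, seed=0)
print(f"labeling accuracy on training targets: {ws.labeling_acc_train:.3f}")
print(ws.label_results.summary())
```

prints

```
balanced training set: 1732 decoys (866 correct)
labeling accuracy on training targets: 0.791
Label model: 4 LFs, 1732 decoys
prior P(correct) = 0.4963   EM iterations = 53   converged = True
LF                     accuracy  propensity
propensity_score         0.7845      0.5064
contact_potential_tsc    0.8694      0.3245
interface_contacts       0.8158      0.3684
surface_energy_model     0.7481      0.4908
```

The greedy selection kept four LFs whose combined votes label 79% of
the balanced training decoys correctly without any access to the gold
labels; `accuracy` is each LF's estimated probability of voting with
the true class when it votes, `propensity` how often it votes at all.

The full study — core classifiers, silver labeling, augmented
retraining on fresh held-out targets — runs in one call:

```python
from haikal.pipeline import run_augmentation_experiment
out = run_augmentation_experiment(seed=1)
```

which yields (seed 1):

```
labeling accuracy (train/val): 0.829 / 0.816
silver labeling accuracy:      0.934
random-forest MCC, core:       0.559
random-forest MCC, augmented:  0.607
top-10 success rate:           1.00
```

The augmented forest beats the core-only forest on held-out targets —
the central claim the pipeline exists to deliver.

A `haikal` command-line interface mirrors the library
(`haikal simulate`, `filter-clashes`, `normalize`, `rank-features`,
`build-lfs`, `select-lfs`, `fit-labelmodel`, `label`, `build-balanced`,
`build-3k`, `assemble-silver`, `merge`, `train`, `predict`, `evaluate`,
`success-rate`); every sampling command takes `--seed`.

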