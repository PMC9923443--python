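# Methods

This note records the models, numerical conventions and design
decisions behind `haikal`, in the order the pipeline runs them.

## Data model and preprocessing

A decoy table is a delimited text file (CSV/TSV, UTF-8, header row) with
id columns `target_id` / `decoy_id`, optional bookkeeping columns
(`program`, `clash_count`, `capri_class`, `binary_label`, weak-label
columns, provenance) and any number of numeric scoring-function columns.
Missing feature values are a hard error rather than being imputed: the
upstream descriptor pipelines produce complete tables, and silent
imputation would corrupt threshold searches. CAPRI quality classes
collapse to binary labels as A/M/H → correct, I → incorrect.

**Clash filter.** Per target, decoys whose clash count strictly exceeds
the target mean plus two standard deviations are dropped. The sample
standard deviation (n−1) is used, matching statistical-package defaults;
equality with the threshold survives (strict inequality), so a target
whose counts are all equal loses nothing. Single-decoy targets cannot
define a spread and are kept with a warning.

**Normalization.** Min–max parameters are fit once on the training rows
and reused unchanged on validation, test and silver tables. Values
outside the training range are *not* clipped — information is preserved
and tree models are insensitive to it — so non-training splits may fall
outside [0, 1]. Constant features are flagged degenerate, normalize to
0, and are excluded from LF candidacy downstream.

## Labeling functions

**Screening.** Features are ranked by Mann–Whitney (midrank-tied) ROC
AUC for correctness. A feature whose raw higher-is-better AUC is below
0.5 is flipped (orientation `lower_is_correct`, AUC = 1 − raw), so every
reported AUC is ≥ 0.5. The screen keeps features with AUC ≥ 0.67 and
truncates to the top 25% of the ranking (both configurable); on a
157-feature panel this keeps at most 40 candidates.

**Threshold search.** For each candidate, every unique observed value is
scanned as a cutoff (a quantile grid can be substituted for very large
n). The correct-side cutoff maximizes `R_corr/(R_Fp + ε)` subject to the
region capturing strictly more than 10% of the correct decoys; the
incorrect side mirrors this with `R_inc/(R_Fn + ε)` and the incorrect
class. `R_Fp = Fp/(Fp+Tp)` and `R_Fn = Fn/(Fn+Tp)` are implemented
exactly in this form (note `R_Fp` is what is conventionally called the
false-discovery rate). The guard ε = 1e−9 means zero-false-positive
cutoffs dominate any impure cutoff, with ties broken by larger capture
and then by the tighter boundary — all deterministic. If the two
selected regions would overlap, both shrink to the midpoint boundary and
the result is flagged; a constant feature yields an infeasible result
rather than an error. Boundary values belong to the decided (voting)
region, matching the histogram-line semantics of a threshold drawn
through a score distribution.

**Selection.** Candidates must individually cover ≥ 10% of each gold
class and ≥ 20% of all decoys. The final subset is chosen greedily to
maximize majority-vote labeling accuracy minus λ·(mean pairwise
overlap), λ = 0.1. Accuracy is scored over *all* rows with abstentions
and ties counting one half — a coin flip — so coverage is rewarded
exactly insofar as the added votes beat chance. When a validation table
(held-out targets) is available the objective is evaluated there, which
removes the in-sample optimism of thresholds tuned on the same rows.
Selection stops early once no remaining candidate improves the
objective, but never below four LFs: experiments on the synthetic
benchmark showed that filling a fixed quota from a candidate pool
dominated by wide, mutually correlated low-accuracy rules collapses the
downstream label model toward random labeling, while a single
high-precision rule leaves most decoys uncovered. Four-to-eight LFs is
where both failure modes are avoided.

## Label model

The aggregator is a two-class conditionally independent Dawid–Skene
model with abstention as an explicit outcome: latent label y ∈ {correct,
incorrect} with prior π, and per LF a 2×3 row-stochastic confusion
matrix θ_j[y, v] = P(v | y), v ∈ {+1, 0, −1}. Modeling the two classes
separately is essential here, not a refinement: threshold LFs are
asymmetric voters (often a wide correct region and a narrow incorrect
region), and a single symmetric accuracy parameter mistakes that
asymmetry for skill, dragging the estimated prior toward the dominant
vote direction until every decoy is labeled with the majority class.

Fitting is EM on the vote matrix alone. Initialization is deterministic
given the seed: responsibilities start from the softened majority vote
plus a tiny seeded jitter. A Dirichlet pseudo-count (0.01) keeps vote
probabilities off zero; the recorded log-likelihood trace is the
corresponding penalized (MAP) objective, which EM makes non-decreasing,
and convergence is declared when it changes by less than 1e−6. The
class prior can be fixed (e.g. at 0.5 on a deliberately balanced
training set) or estimated; reported scalar accuracies are clamped to
(0.51, 0.99) so no LF is treated as certain. Posterior prediction
labels at the 0.5 cutoff with ties resolved to incorrect (conservative
for downstream balanced sampling); all-abstain decoys receive the class
prior and are flagged, so every decoy gets a label.

**Prior shift.** A prior fitted on a balanced training set does not
transfer to an arbitrary decoy population. `adapted_prior` re-estimates
π on a new vote population by fixed-point EM with the confusions held
fixed (the classic prior-shift correction).

**Prevalence quantification.** `estimate_prevalence` implements
adjusted-count quantification: for an LF with gold-measured vote rates
TPR = P(+1 | correct), FPR = P(+1 | incorrect), the observed +1 rate on
a new population is TPR·π + FPR·(1−π); solving for π and taking the
median over LFs separated by at least 0.1 gives a prevalence estimate
that is robust to a minority of misbehaving LFs and, unlike the label
model's own prior, does not inherit the EM confusions' optimism.

## Silver labeling policy

The silver corpus (decoys of complexes without experimental structures)
is labeled in a deliberately conservative, per-target way
(`label_silver_conservative`): estimate each target's correct-class
prevalence π̂ by quantification, label as correct only the top ½·π̂
fraction of the target's decoys ranked by label-model posterior, hold
out decoys ranked within 1.5·π̂ as borderline, and label the remainder
incorrect. The factor ½ trades recall for precision and the borderline
band keeps near-threshold decoys out of both training pools.

This policy is the pipeline's load-bearing design decision. Three
alternatives were evaluated on the synthetic benchmark across
independent seed batches: thresholding the posterior at 0.5 (with or
without prior adaptation) intermittently overcalls the correct class
two-to-threefold when the EM confusions are optimistic, poisoning the
augmented training set; labeling exactly the estimated prevalence
(calibrated but not conservative) includes the ambiguous boundary
decoys and performs worst of all; the conservative policy produced a
weak-correct class of 85–96% precision in every seed examined, and the
augmented-versus-core comparison went from a coin flip to a near-uniform
win. The general lesson it encodes: augmentation quality is governed by
the precision of the minority (correct) class, not by label-count
calibration — exactly the abstention philosophy of the LFs, applied
once more at the corpus level.

## Dataset builders

Balanced sets keep, per target, min(#correct, 600) correct decoys and an
equal-size uniform undersample (without replacement) of incorrect
decoys; targets without correct decoys are dropped and reported. If a
target has fewer incorrect than capped correct decoys, the pair size
shrinks so the set stays exactly 50/50. 3K sets keep up to 600 correct
and fill with random incorrect decoys to 3000 per target, taking
everything (with a flag) when a target is too small. All sampling is
driven by a single seeded generator over targets in sorted order, so a
seed reproduces the selection bit-exactly. Silver assembly takes the
top-N (default 1000) decoys per target from each program's ranking,
keeps cross-program duplicates by default (a switch deduplicates), and
reports the overlap between a designated pair of selections against both
denominators (the top-N slice and the pair union). Merging core and
silver requires identical feature schemas and tags provenance
(core/silver) and label provenance (gold/weak).

## Classifiers

Three families, all through scikit-learn: `perceptron` — a single
logistic unit trained by stochastic gradient updates (SGDClassifier,
log loss, no penalty); `dense-net` — MLPClassifier with three processing
layers (64, 32, 16), L2 penalty 1e−3, learning rate 0.01, early stopping
on a 10% validation split (regularisation by weight decay plus early
stopping rather than dropout — the claim the pipeline tests is relative
between training sets, not architecture-specific); `random-forest` —
100 trees. Forest and perceptron are bit-deterministic given the seed;
the dense net is seeded with small residual variation from its internal
validation split tolerated downstream. The class-probability
augmentation appends the three core-trained classifiers' probabilities
of correctness as the last three features, unnormalized since they
already live in [0, 1]. In the augmentation experiment the comparison
classifier's own class probability is barred from LF candidacy, so the
final classifier never consumes labels distilled from its own
predictions.

## Evaluation

Confusion metrics treat correct as the positive class and implement the
eight standard quantities; any zero denominator yields 0 for that metric
with a degeneracy flag (including an MCC denominator of zero). The
success rate ranks each target's decoys by descending score with ties
broken by ascending decoy id, and counts targets with at least one
correct decoy in the top N ∈ {1, 10, 100}; targets without any correct
decoy are excluded from the denominator and reported.

## Synthetic benchmark

The generator emulates a scored decoy corpus. Per decoy, a binary label
is drawn from the target's prevalence (itself drawn per target from a
configurable range, default 2–40%, mimicking the wildly variable correct
fractions of real ensembles). Each scoring function is a
class-conditional Gaussian whose means are separated by
d = √2·Φ⁻¹(AUC) at unit noise variance, so its marginal AUC equals its
specification; orientation decides the sign. The noise decomposes into
√ρ times a shared per-decoy factor plus √(1−ρ) independent noise, with
the shared factor entering every feature *aligned with the feature's
orientation*: it behaves as a generic "plausibility" confounder (think
interface size or compactness) that all scoring functions mistake for
quality. Because no feature combination can cancel it without cancelling
the signal, it caps the jointly achievable accuracy the way real
scoring-function panels plateau — with ρ = 0.3 and the default panel
the forest ceiling sits near MCC 0.7, the regime real docking
classifiers occupy — while leaving every per-feature marginal exactly as
specified. A per-target, per-feature offset (SD 0.2) adds the systematic
score shifts real targets exhibit, and Poisson clash counts with a 1%
outlier fraction at 20× the rate exercise the clash filter. A
heavier-tailed noise family (scaled Student t) is available to stress
the threshold search.

The default panel holds 24 scoring functions with AUCs 0.65–0.92 in a
descending post-screen-style ranking, mixed orientations, mirroring a
realistic public panel: one strong consensus score, a spread of mid
potentials, weak descriptors a sound selection should discard. The
strongest LF candidates of a full study — classifier class
probabilities — are not generated; the pipeline derives them by
training on the panel, as a real study would.

**Scale of the packaged experiment.** `run_augmentation_experiment`
uses 16 core targets (12 train / 4 validation), 48 silver targets, 12
test targets at 250 decoys each — a deliberate desk-scale reduction of
the corpora such pipelines run on (hundreds of gold targets, thousands
of silver targets, thousands of decoys each) that keeps the qualitative
ratios: silver targets several-fold more numerous than core, test
targets disjoint from both, silver and test prevalences unbalanced.

**What passing tests do and do not show.** The synthetic world is
Gaussian, stationary within targets, and its confounder structure is
known; real scoring functions have heavy tails, inter-target
heterogeneity beyond mean shifts, and dependencies the label model does
not represent. Green tests establish that every stage implements its
contract and that the augmentation mechanism works end-to-end when its
assumptions hold approximately; they do not certify effect sizes on any
real decoy corpus.

## Known limitations

- The label model assumes conditional independence of LF votes given
  the true label; correlated LFs inflate each other's estimated
  reliability. The overlap penalty at selection time and the
  conservative silver policy mitigate but do not remove this.
- Threshold LFs built from Gaussian mid-AUC features rarely possess
  pure tails, so their searched regions are wide and their stand-alone
  accuracy modest; on real, heavy-tailed scores the same search yields
  sharper rules.
- The dense net is not bit-reproducible across BLAS builds; tests
  assert its behaviour only up to thresholds.
- `estimate_prevalence` assumes the LFs' class-conditional vote rates
  transfer from the (gold) training targets to the silver population;
  strong covariate shift degrades the estimate, which the clipping to
  [0.01, 0.6] only bounds.
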