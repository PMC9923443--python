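"""End-to-end weak-supervision and augmentation workflows.

Ties the stages together the way a full study runs them:

1. rank scoring functions by AUC on the gold-labeled balanced training
   set, screen candidates, search per-feature vote thresholds and select
   the final LF subset;
2. fit the generative label model on the training vote matrix and check
   its labeling accuracy on training and validation targets;
3. mass-label the silver decoys, balance them per target on their weak
   labels, and merge with the core set;
4. train the classifier families on core vs augmented data (the augmented
   table carries the three core class probabilities as extra features)
   and compare on held-out targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifiers as clf
from . import core_data as cd
from . import dataset_builder as db
from . import evaluation as ev
from . import label_model as lm
from . import lf_engine as lfe
from . import synthetic_data as sd

__all__ = [
    "WeakSupervisionResult",
    "run_weak_supervision",
    "label_silver_conservative",
    "run_augmentation_experiment",
]


@dataclass
class WeakSupervisionResult:
    """Everything the weak-supervision stage produces."""

    ranking: lfe.FeatureRanking
    candidates: list[str]
    lfs: list[lfe.LabelingFunction]
    label_results: lm.LabelModelResults
    train_labeling: lm.WeakLabeling
    labeling_acc_train: float
    labeling_acc_val: float | None = None
    diagnostics: lfe.LFDiagnostics | None = None


def run_weak_supervision(
    train_table: cd.FeatureTable,
    val_table: cd.FeatureTable | None = None,
    auc_min: float = 0.67,
    top_fraction: float = 0.25,
    min_class_cov: float = 0.10,
    k: int = 8,
    lam: float = 0.1,
    seed: int = 0,
    lf_exclude: tuple[str, ...] = (),
    stop_on_no_gain: bool = True,
    min_k: int = 4,
) -> WeakSupervisionResult:
    """Build LFs from the labeled training table and fit the label model.

    ``train_table`` must carry binary labels.  Thresholds are searched on
    the training table; the final greedy LF selection is scored on
    ``val_table`` when given (held-out targets give an unbiased estimate
    of labeling quality), otherwise on the training table, and stops
    early once no candidate improves the objective (but keeps at least
    ``min_k`` LFs).  ``lf_exclude`` bars named features from LF candidacy
    (e.g. the class probability of the classifier family that will
    consume the weak labels downstream).
    """
    y = np.asarray(train_table.labels, dtype=bool)
    ranking = lfe.rank_features_by_auc(train_table, y)
    candidates = [
        c
        for c in lfe.screen_features(ranking, auc_min, top_fraction)
        if c not in lf_exclude
    ]
    results = []
    for name in candidates:  # candidates are in AUC-rank order
        res = lfe.find_thresholds(
            train_table.df[name].to_numpy(float),
            y,
            orientation=ranking.orientation(name),
            min_class_cov=min_class_cov,
            feature_name=name,
        )
        if res.feasible:
            results.append(res)
    lfs_all = [lfe.build_lf(r) for r in results]
    select_table = val_table if val_table is not None else train_table
    lfs = lfe.select_lfs(
        lfs_all,
        select_table,
        np.asarray(select_table.labels, dtype=bool),
        k=k,
        lam=lam,
        min_class_cov=min_class_cov,
        stop_on_no_gain=stop_on_no_gain,
        min_k=min_k,
    )
    if len(lfs) < 2:
        raise ValueError("fewer than 2 usable labeling functions")
    matrix = lfe.build_lf_matrix(lfs, train_table)
    diagnostics = lfe.lf_diagnostics(
        matrix, y, names=[lf.feature_name for lf in lfs]
    )
    model = lm.LabelModel(matrix, [lf.feature_name for lf in lfs])
    fitted = model.fit(seed=seed)
    train_pred = fitted.predict()
    acc_train, _ = lm.labeling_accuracy(train_pred, y)
    acc_val = None
    if val_table is not None:
        vm = lfe.build_lf_matrix(lfs, val_table)
        val_pred = fitted.predict(vm)
        acc_val, _ = lm.labeling_accuracy(
            val_pred, np.asarray(val_table.labels, dtype=bool)
        )
    return WeakSupervisionResult(
        ranking=ranking,
        candidates=candidates,
        lfs=lfs,
        label_results=fitted,
        train_labeling=train_pred,
        labeling_acc_train=acc_train,
        labeling_acc_val=acc_val,
        diagnostics=diagnostics,
    )


def label_silver_conservative(
    ws: WeakSupervisionResult,
    train_table: cd.FeatureTable,
    silver_table: cd.FeatureTable,
    conservatism: float = 0.5,
    exclusion: float = 1.5,
    max_prevalence: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, lm.WeakLabeling]:
    """High-precision weak labels for an unlabeled silver corpus.

    Per silver target, the correct-class prevalence is estimated by
    adjusted-count quantification from the LFs' gold-measured vote rates
    on the training table (:func:`haikal.label_model.estimate_prevalence`),
    then only the top ``conservatism`` fraction of that estimated correct
    mass — ranked by label-model posterior — is labeled correct, and
    decoys ranked inside ``exclusion`` times the estimated mass are held
    out of the incorrect pool as borderline.  Trading recall for
    precision this way mirrors the abstention philosophy of the LFs
    themselves: a polluted correct class hurts a downstream classifier
    far more than a smaller, cleaner one.

    Returns ``(labels, keep, posterior)``: boolean correct labels, a
    boolean mask of decoys confidently labeled either way (borderline
    band excluded), and the raw posterior labeling.
    """
    votes_train = lfe.build_lf_matrix(ws.lfs, train_table)
    y_train = np.asarray(train_table.labels, dtype=bool)
    tpr = (votes_train[y_train] == 1).mean(axis=0)
    fpr = (votes_train[~y_train] == 1).mean(axis=0)

    votes = lfe.build_lf_matrix(ws.lfs, silver_table)
    posterior = ws.label_results.predict(votes)
    targets = silver_table.df["target_id"].to_numpy()
    labels = np.zeros(len(silver_table), dtype=bool)
    keep = np.zeros(len(silver_table), dtype=bool)
    fallback = ws.label_results.adapted_prior(votes)
    for tid in np.unique(targets):
        rows = np.flatnonzero(targets == tid)
        pi = lm.estimate_prevalence(votes[rows], tpr, fpr)
        if pi is None:
            pi = fallback
        pi = float(np.clip(pi, 0.01, max_prevalence))
        n_corr = int(round(conservatism * pi * len(rows)))
        n_excl = int(round(exclusion * pi * len(rows)))
        order = rows[np.argsort(-posterior.prob[rows], kind="stable")]
        labels[order[:n_corr]] = True
        keep[order[:n_corr]] = True
        keep[order[n_excl:]] = True
    return labels, keep, posterior


def _mcc_of(model: clf.TrainedModel, table: cd.FeatureTable, y) -> float:
    prob = clf.predict_proba(model, table)
    counts = ev.confusion_counts(prob > 0.5, y)
    return ev.compute_metrics(counts).mcc


def run_augmentation_experiment(
    seed: int = 0,
    n_core_targets: int = 16,
    n_silver_targets: int = 48,
    n_test_targets: int = 12,
    decoys_per_target: int = 250,
    core_prevalence=(0.05, 0.4),
    silver_prevalence=(0.02, 0.4),
    test_prevalence=(0.05, 0.2),
    n_val_targets: int = 4,
    kinds=("perceptron", "dense-net", "random-forest"),
    compare_kind: str = "random-forest",
    auc_min: float = 0.6,
    top_fraction: float = 1.0,
    k: int = 8,
    target_effect_sd: float | None = None,
) -> dict:
    """One full synthetic augmentation study at a given seed.

    Generates a gold-labeled core corpus (split into training and
    validation targets), an unlabeled silver corpus with withheld truth,
    and a held-out test corpus; trains the core classifiers and appends
    their class probabilities as features (the strongest LF candidates, as
    in a full study); runs weak supervision, silver labeling,
    balanced-set construction and augmented training; returns the
    headline quantities (labeling accuracies, silver accuracy against the
    withheld truth, core vs augmented MCC of ``compare_kind``, top-N
    success rates on the unbalanced test set).

    The class probability of ``compare_kind`` itself is barred from LF
    candidacy so the final classifier does not consume labels distilled
    from its own core predictions.  The synthetic feature panel plays the
    role of the already-screened candidate set, so the screen keeps the
    whole panel by default.
    """
    rng = np.random.default_rng(seed)
    s_core, s_silver, s_test, s_fit = rng.integers(0, 2**31 - 1, size=4)
    sd_kw = {} if target_effect_sd is None else {
        "target_effect_sd": target_effect_sd
    }

    core = sd.generate(
        sd.SyntheticConfig(
            n_targets=n_core_targets,
            decoys_per_target=decoys_per_target,
            prevalence=core_prevalence,
            seed=int(s_core),
            **sd_kw,
        )
    )
    silver = sd.generate(
        sd.SyntheticConfig(
            n_targets=n_silver_targets,
            decoys_per_target=decoys_per_target,
            prevalence=silver_prevalence,
            seed=int(s_silver),
            **sd_kw,
        )
    )
    test = sd.generate(
        sd.SyntheticConfig(
            n_targets=n_test_targets,
            decoys_per_target=decoys_per_target,
            prevalence=test_prevalence,
            seed=int(s_test),
            **sd_kw,
        )
    )
    # silver/test targets get distinct ids so the merge keeps them apart
    silver = cd.FeatureTable(
        silver.df.assign(target_id="S" + silver.df["target_id"])
    )
    test = cd.FeatureTable(test.df.assign(target_id="E" + test.df["target_id"]))

    core, _ = cd.filter_clashes(core)
    silver, _ = cd.filter_clashes(silver)

    all_core_targets = sorted(core.df["target_id"].unique())
    val_targets = all_core_targets[-n_val_targets:]
    val_tab, train_tab = cd.split_by_targets(core, val_targets)

    norm = cd.fit_minmax(train_tab, np.ones(len(train_tab), bool))
    train_n = cd.apply_minmax(train_tab, norm)
    val_n = cd.apply_minmax(val_tab, norm)
    silver_n = cd.apply_minmax(silver, norm)
    test_n = cd.apply_minmax(test, norm)

    bal_train, _ = db.build_balanced(train_n, seed=int(s_fit))
    bal_val, _ = db.build_balanced(val_n, seed=int(s_fit) + 1)

    # core classifiers on the balanced gold training set (raw features);
    # their class probabilities become the last three features everywhere
    core_models = [
        clf.train_classifier(clf.ClassifierSpec(kind, seed=int(s_fit)), bal_train)
        for kind in kinds
    ]
    bal_train_aug = clf.augment_with_class_probs(bal_train, core_models)
    bal_val_aug = clf.augment_with_class_probs(bal_val, core_models)
    silver_aug = clf.augment_with_class_probs(silver_n, core_models)
    test_aug = clf.augment_with_class_probs(test_n, core_models)

    ws = run_weak_supervision(
        bal_train_aug,
        bal_val_aug,
        auc_min=auc_min,
        top_fraction=top_fraction,
        k=k,
        seed=int(s_fit),
        lf_exclude=(f"class_prob_{compare_kind}",),
    )

    # mass-label the silver decoys; withheld truth only scores the result
    silver_labels, silver_keep, silver_post = label_silver_conservative(
        ws, bal_train_aug, silver_aug
    )
    silver_truth = np.asarray(silver_aug.labels, dtype=bool)
    silver_acc_covered = float(
        (silver_labels[silver_keep] == silver_truth[silver_keep]).mean()
    )
    silver_acc_all = float((silver_labels == silver_truth).mean())
    silver_weak = cd.FeatureTable(
        silver_aug.df.loc[silver_keep]
        .reset_index(drop=True)
        .drop(columns=["capri_class", "binary_label"])
        .assign(
            binary_label=np.where(
                silver_labels[silver_keep], cd.CORRECT, cd.INCORRECT
            ),
        )
    )

    # augmented training: balanced silver (weak labels) + balanced core
    bal_silver, _ = db.build_balanced(silver_weak, seed=int(s_fit) + 2)
    merged, merge_report = db.merge_augmented(bal_train_aug, bal_silver)
    aug_models = [
        clf.train_classifier(
            clf.ClassifierSpec(kind, seed=int(s_fit)),
            merged,
            provenance="augmented",
        )
        for kind in kinds
    ]

    test_y = np.asarray(test_n.labels, dtype=bool)
    idx = list(kinds).index(compare_kind)
    mcc_core = _mcc_of(core_models[idx], test_n, test_y)
    mcc_aug = _mcc_of(aug_models[idx], test_aug, test_y)

    score_df = test_n.df[["target_id", "decoy_id", "binary_label"]].copy()
    score_df["score"] = clf.predict_proba(aug_models[idx], test_aug)
    sr = ev.success_rate(score_df)

    return {
        "weak_supervision": ws,
        "labeling_acc_train": ws.labeling_acc_train,
        "labeling_acc_val": ws.labeling_acc_val,
        "silver_acc_covered": silver_acc_covered,
        "silver_acc_all": silver_acc_all,
        "silver_correct_pct": 100.0 * float(silver_labels.mean()),
        "silver_labeled_fraction": float(silver_keep.mean()),
        "merge_report": merge_report,
        "mcc_core": mcc_core,
        "mcc_augmented": mcc_aug,
        "success_rate": sr,
    }
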