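"""Labeling functions from scoring-function thresholds.

Each scoring function (feature) becomes a candidate *labeling function*
(LF): a rule with two thresholds that votes ``correct`` on one tail of the
feature's distribution, ``incorrect`` on the other tail, and abstains in
between.  The thresholds are found by a constrained ratio search over the
observed values:

* correct side: maximize  R_corr / R_Fp  subject to Tp covering more than
  ``min_class_cov`` of the correct decoys, where R_corr = Tp/(Tp+Fn) is the
  recall of correct decoys and R_Fp = Fp/(Fp+Tp) is the false-positive
  recall of the thresholded rule;
* incorrect side: maximize  R_inc / R_Fn  subject to Tn covering more than
  ``min_class_cov`` of the incorrect decoys, with R_inc = Tn/(Tn+Fp) and
  R_Fn = Fn/(Fn+Tp).

Features are screened beforehand by ROC AUC, and the final LF subset is
chosen greedily for labeling accuracy while penalising pairwise overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import FeatureTable

__all__ = [
    "HIGHER_IS_CORRECT",
    "LOWER_IS_CORRECT",
    "FeatureRanking",
    "ThresholdSearchResult",
    "LabelingFunction",
    "LFDiagnostics",
    "rank_features_by_auc",
    "screen_features",
    "find_thresholds",
    "build_lf",
    "apply_lf",
    "build_lf_matrix",
    "lf_diagnostics",
    "select_lfs",
    "lfs_to_text",
    "lfs_from_text",
]

HIGHER_IS_CORRECT = "higher_is_correct"
LOWER_IS_CORRECT = "lower_is_correct"

#: Added to ratio denominators so zero-false-positive cutoffs are rewarded.
EPS = 1e-9


# ---------------------------------------------------------------------------
# AUC ranking and screening


@dataclass
class FeatureRanking:
    """Per-feature oriented AUC ranking, sorted descending by AUC.

    ``table`` has columns ``feature``, ``auc`` (post-orientation, >= 0.5),
    ``orientation`` and ``rank`` (1 = best).
    """

    table: pd.DataFrame

    def orientation(self, feature: str) -> str:
        return self.table.set_index("feature").loc[feature, "orientation"]

    def auc(self, feature: str) -> float:
        return float(self.table.set_index("feature").loc[feature, "auc"])


def _auc_mann_whitney(values: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC of `values` for class y (True = correct), higher-is-correct.

    Rank-statistic (Mann-Whitney) formulation with midranks for ties.
    """
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(values)
    return (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def rank_features_by_auc(table: FeatureTable, labels=None) -> FeatureRanking:
    """Rank all features by their (oriented) ROC AUC for correctness.

    Features whose raw higher-is-correct AUC falls below 0.5 are reported
    flipped: orientation ``lower_is_correct`` with auc = 1 - raw, so every
    reported AUC is >= 0.5.  Sorted descending by AUC; ties broken by
    feature name for determinism.
    """
    y = np.asarray(table.labels if labels is None else labels, dtype=bool)
    if len(y) != len(table):
        raise ValueError("labels misaligned with table")
    rows = []
    for name in table.feature_names:
        raw = _auc_mann_whitney(table.df[name].to_numpy(dtype=float), y)
        if raw >= 0.5:
            rows.append((name, raw, HIGHER_IS_CORRECT))
        else:
            rows.append((name, 1.0 - raw, LOWER_IS_CORRECT))
    df = pd.DataFrame(rows, columns=["feature", "auc", "orientation"])
    df = df.sort_values(
        ["auc", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return FeatureRanking(df)


def screen_features(
    ranking: FeatureRanking,
    auc_min: float = 0.67,
    top_fraction: float = 0.25,
) -> list[str]:
    """Keep features with AUC >= auc_min, truncated to the top fraction.

    With the defaults and 157 features this keeps at most
    ceil(0.25 * 157) = 40 candidates.
    """
    if ranking.table.empty:
        raise ValueError("empty feature ranking")
    cap = math.ceil(top_fraction * len(ranking.table))
    kept = ranking.table[ranking.table["auc"] >= auc_min].head(cap)
    names = kept["feature"].tolist()
    if not names:
        warnings.warn("no feature passed the AUC screen", stacklevel=2)
    return names


# ---------------------------------------------------------------------------
# Threshold-ratio search


@dataclass
class ThresholdSearchResult:
    """Outcome of the two-sided constrained threshold search for one feature.

    ``t_correct``/``t_incorrect`` delimit the correct and incorrect vote
    regions (boundaries inclusive); ``correct_ratio``/``incorrect_ratio``
    are the attained values of the two objective ratios;
    ``tp_fraction``/``tn_fraction`` are the fractions of each class covered
    by its region.  ``feasible`` is False when no cutoff satisfies a
    coverage constraint; ``overlap_adjusted`` marks results whose regions
    initially overlapped and were shrunk to the midpoint boundary.
    """

    feature_name: str
    orientation: str
    t_correct: float = math.nan
    t_incorrect: float = math.nan
    correct_ratio: float = math.nan
    incorrect_ratio: float = math.nan
    tp_fraction: float = math.nan
    tn_fraction: float = math.nan
    feasible: bool = False
    overlap_adjusted: bool = False


def find_thresholds(
    values,
    labels,
    orientation: str = HIGHER_IS_CORRECT,
    grid=None,
    min_class_cov: float = 0.10,
    feature_name: str = "",
) -> ThresholdSearchResult:
    """Search both vote-region cutoffs for one feature.

    Scans candidate cutoffs (default: every unique observed value, or the
    supplied ``grid``) and returns the constrained argmax for each side.
    If the two selected regions would overlap, both are shrunk to the
    midpoint boundary and the result is marked ``overlap_adjusted``.
    Constant features yield an infeasible result rather than an error.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(v) != len(y):
        raise ValueError("values and labels misaligned")
    n_corr = int(y.sum())
    n_inc = len(y) - n_corr
    if n_corr == 0 or n_inc == 0:
        raise ValueError("both classes must be present")

    res = ThresholdSearchResult(feature_name, orientation)
    # work in oriented space: lower value -> more likely correct
    w = -v if orientation == HIGHER_IS_CORRECT else v
    if grid is not None:
        g = np.asarray(grid, dtype=float)
        wgrid = -g if orientation == HIGHER_IS_CORRECT else g
    else:
        wgrid = None
    if np.unique(w).size < 2:
        return res  # degenerate: infeasible

    corr = _search_corr(w, y, n_corr, min_class_cov, wgrid)
    inc = _search_inc(w, y, n_corr, n_inc, min_class_cov, wgrid)
    if corr is None or inc is None:
        return res

    t_c, ratio_c, cov_c = corr
    t_i, ratio_i, cov_i = inc
    if t_c >= t_i:  # regions overlap: shrink to midpoint boundary
        mid = (t_c + t_i) / 2.0
        t_c = mid
        t_i = float(np.nextafter(mid, np.inf))
        res.overlap_adjusted = True
        cov_c = float((w[y] <= t_c).mean())
        cov_i = float((w[~y] >= t_i).mean())
    res.feasible = True
    res.correct_ratio = ratio_c
    res.incorrect_ratio = ratio_i
    res.tp_fraction = cov_c
    res.tn_fraction = cov_i
    # map back to the raw-value scale
    if orientation == HIGHER_IS_CORRECT:
        res.t_correct, res.t_incorrect = -t_c, -t_i
    else:
        res.t_correct, res.t_incorrect = t_c, t_i
    return res


def _search_corr(w, y, n_corr, min_cov, grid=None):
    """Correct-side cutoff: region w <= t predicts correct.

    Maximizes R_corr/(R_Fp + eps) with Tp > min_cov * n_corr (strict).
    Ties broken by larger Tp, then by the tighter (smaller) cutoff.
    """
    cands = np.unique(w) if grid is None else np.unique(grid)
    best = None
    for t in cands:
        in_region = w <= t
        tp = int((in_region & y).sum())
        fp = int((in_region & ~y).sum())
        if tp <= min_cov * n_corr:
            continue
        r_corr = tp / n_corr
        r_fp = fp / (fp + tp) if (fp + tp) else 0.0
        ratio = r_corr / (r_fp + EPS)
        key = (ratio, tp, -t)
        if best is None or key > best[0]:
            best = (key, float(t), ratio, r_corr)
    return None if best is None else best[1:]


def _search_inc(w, y, n_corr, n_inc, min_cov, grid=None):
    """Incorrect-side cutoff: region w >= t predicts incorrect.

    Maximizes R_inc/(R_Fn + eps) with Tn > min_cov * n_inc (strict), where
    R_Fn = Fn/(Fn+Tp) counts correct decoys caught in the region (Fn)
    against correct decoys left outside it (Tp).
    Ties broken by larger Tn, then by the tighter (larger) cutoff.
    """
    cands = np.unique(w) if grid is None else np.unique(grid)
    best = None
    for t in cands:
        in_region = w >= t
        tn = int((in_region & ~y).sum())
        fn = int((in_region & y).sum())
        tp_out = n_corr - fn
        if tn <= min_cov * n_inc:
            continue
        r_inc = tn / n_inc
        r_fn = fn / (fn + tp_out) if (fn + tp_out) else 0.0
        ratio = r_inc / (r_fn + EPS)
        key = (ratio, tn, t)
        if best is None or key > best[0]:
            best = (key, float(t), ratio, r_inc)
    return None if best is None else best[1:]


# ---------------------------------------------------------------------------
# Labeling functions


@dataclass
class LabelingFunction:
    """A two-threshold abstaining vote rule on one feature.

    For ``lower_is_correct`` orientation: value <= t_correct votes +1
    (correct), value >= t_incorrect votes -1 (incorrect), anything in
    between abstains (0).  Mirrored for ``higher_is_correct``.  Boundary
    values belong to the decided region.
    """

    feature_name: str
    orientation: str
    t_correct: float
    t_incorrect: float
    provenance: ThresholdSearchResult | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if self.orientation == LOWER_IS_CORRECT:
            ok = self.t_correct < self.t_incorrect
        else:
            ok = self.t_correct > self.t_incorrect
        if not ok:
            raise ValueError(
                "correct and incorrect regions overlap for "
                f"{self.feature_name!r}"
            )

    def __call__(self, values) -> np.ndarray:
        return apply_lf(self, values)


def build_lf(result: ThresholdSearchResult) -> LabelingFunction:
    """Construct a LabelingFunction from a feasible threshold search."""
    if not result.feasible:
        raise ValueError(f"infeasible threshold search: {result.feature_name!r}")
    return LabelingFunction(
        result.feature_name,
        result.orientation,
        result.t_correct,
        result.t_incorrect,
        provenance=result,
    )


def apply_lf(lf: LabelingFunction, values) -> np.ndarray:
    """Vectorized three-way vote: +1 correct, -1 incorrect, 0 abstain."""
    v = np.asarray(values, dtype=float)
    votes = np.zeros(v.shape, dtype=np.int8)
    if lf.orientation == LOWER_IS_CORRECT:
        votes[v <= lf.t_correct] = 1
        votes[v >= lf.t_incorrect] = -1
    else:
        votes[v >= lf.t_correct] = 1
        votes[v <= lf.t_incorrect] = -1
    return votes


def build_lf_matrix(lfs: list[LabelingFunction], table: FeatureTable) -> np.ndarray:
    """Stack LF votes into a decoys x LFs matrix with entries {-1, 0, +1}."""
    cols = [apply_lf(lf, table.df[lf.feature_name].to_numpy(float)) for lf in lfs]
    return np.column_stack(cols) if cols else np.empty((len(table), 0), np.int8)


def lfs_to_text(lfs: list[LabelingFunction]) -> str:
    """One LF per line: feature, orientation, t_correct, t_incorrect."""
    return "".join(
        f"{lf.feature_name}\t{lf.orientation}\t{lf.t_correct!r}\t{lf.t_incorrect!r}\n"
        for lf in lfs
    )


def lfs_from_text(text: str) -> list[LabelingFunction]:
    lfs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        name, orient, tc, ti = line.split("\t")
        lfs.append(LabelingFunction(name, orient, float(tc), float(ti)))
    return lfs


# ---------------------------------------------------------------------------
# Diagnostics and final selection


@dataclass
class LFDiagnostics:
    """Coverage / accuracy / overlap diagnostics of an LF set.

    ``per_lf`` columns: coverage (fraction of decoys with a vote),
    corr_coverage and inc_coverage (fraction of each gold class with a
    vote; NaN without labels), accuracy (empirical, on voted labeled rows).
    ``overlap``/``conflict`` are LF x LF fractions of decoys where both
    vote / where their votes disagree.
    """

    per_lf: pd.DataFrame
    overlap: np.ndarray
    conflict: np.ndarray


def lf_diagnostics(matrix: np.ndarray, labels=None, names=None) -> LFDiagnostics:
    """Compute coverage, per-class coverage, accuracy, overlap and conflict."""
    m = np.asarray(matrix)
    if m.size == 0:
        raise ValueError("empty LF matrix")
    n, k = m.shape
    voted = m != 0
    coverage = voted.mean(axis=0)
    if labels is not None:
        y = np.asarray(labels, dtype=bool)
        pos, neg = y, ~y
        corr_cov = voted[pos].mean(axis=0) if pos.any() else np.full(k, np.nan)
        inc_cov = voted[neg].mean(axis=0) if neg.any() else np.full(k, np.nan)
        truth = np.where(y, 1, -1)[:, None]
        hits = (m == truth) & voted
        with np.errstate(invalid="ignore"):
            acc = hits.sum(axis=0) / voted.sum(axis=0)
    else:
        corr_cov = inc_cov = acc = np.full(k, np.nan)
    per_lf = pd.DataFrame(
        {
            "name": names if names is not None else [f"lf{i}" for i in range(k)],
            "coverage": coverage,
            "corr_coverage": corr_cov,
            "inc_coverage": inc_cov,
            "accuracy": acc,
        }
    )
    overlap = np.zeros((k, k))
    conflict = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            both = voted[:, i] & voted[:, j]
            overlap[i, j] = both.mean()
            conflict[i, j] = (both & (m[:, i] != m[:, j])).mean()
    return LFDiagnostics(per_lf, overlap, conflict)


def _majority_accuracy(matrix: np.ndarray, y: np.ndarray) -> float:
    """Majority-vote labeling accuracy over all rows.

    Ties and uncovered rows count half (a coin flip), so the score
    rewards coverage only insofar as the added votes beat chance.
    """
    s = matrix.sum(axis=1)
    truth = np.where(y, 1, -1)
    hit = np.where(s == 0, 0.5, (np.sign(s) == truth).astype(float))
    return float(hit.mean())


def select_lfs(
    candidates: list[LabelingFunction],
    table: FeatureTable,
    labels=None,
    k: int = 8,
    lam: float = 0.1,
    min_class_cov: float = 0.10,
    min_total_cov: float = 0.20,
    stop_on_no_gain: bool = False,
    min_k: int = 2,
) -> list[LabelingFunction]:
    """Greedy forward selection of the final LF subset.

    Candidates must individually cover >= ``min_class_cov`` of each gold
    class and >= ``min_total_cov`` of all decoys.  The greedy objective is
    majority-vote labeling accuracy on the labeled table minus
    ``lam`` x (mean pairwise overlap of the chosen set); ties break by
    candidate order (callers pass candidates in AUC-rank order).  By
    default the selection fills all ``k`` slots (coverage of the eventual
    vote matrix matters as much as training accuracy); with
    ``stop_on_no_gain`` it stops once no remaining candidate improves the
    objective (but never before ``min_k`` LFs), so the returned objective
    is never below the best single candidate's.
    """
    y = np.asarray(table.labels if labels is None else labels, dtype=bool)
    votes = {
        lf.feature_name: apply_lf(lf, table.df[lf.feature_name].to_numpy(float))
        for lf in candidates
    }
    feasible = []
    for lf in candidates:
        v = votes[lf.feature_name]
        voted = v != 0
        if voted.mean() < min_total_cov:
            continue
        if voted[y].mean() < min_class_cov or voted[~y].mean() < min_class_cov:
            continue
        feasible.append(lf)
    if len(feasible) < k:
        warnings.warn(
            f"only {len(feasible)} feasible LF candidates (requested {k})",
            stacklevel=2,
        )
        k = len(feasible)

    chosen: list[LabelingFunction] = []
    chosen_votes: list[np.ndarray] = []

    def objective(extra_votes):
        cols = chosen_votes + [extra_votes]
        m = np.column_stack(cols)
        acc = _majority_accuracy(m, y)
        kk = len(cols)
        if kk < 2:
            mean_overlap = 0.0
        else:
            voted = m != 0
            tot, cnt = 0.0, 0
            for i in range(kk):
                for j in range(i + 1, kk):
                    tot += (voted[:, i] & voted[:, j]).mean()
                    cnt += 1
            mean_overlap = tot / cnt
        return acc - lam * mean_overlap

    remaining = list(feasible)
    current = -np.inf
    while len(chosen) < k and remaining:
        # a duplicate LF adds no information, only redundant votes
        remaining = [lf for lf in remaining if lf not in chosen]
        if not remaining:
            break
        scores = [objective(votes[lf.feature_name]) for lf in remaining]
        best = int(np.argmax(scores))  # argmax keeps first on ties: AUC order
        if stop_on_no_gain and len(chosen) >= min_k and scores[best] < current:
            break
        current = scores[best]
        chosen.append(remaining[best])
        chosen_votes.append(votes[remaining[best].feature_name])
        remaining.pop(best)
    return chosen
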