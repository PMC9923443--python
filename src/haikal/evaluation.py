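"""Confusion-matrix metrics and per-target top-N success rate.

The eight global metrics are the per-class precisions, recalls and F1
scores, accuracy and the Matthews correlation coefficient (MCC), computed
with the correct class as positive:

    P_corr = Tp/(Tp+Fp)      P_inc = Tn/(Tn+Fn)
    R_corr = Tp/(Tp+Fn)      R_inc = Tn/(Tn+Fp)
    F1     = 2 P R / (P + R) per class
    Acc    = (Tp+Tn)/n
    MCC    = (Tp*Tn - Fp*Fn) / sqrt((Tp+Fp)(Tp+Fn)(Tn+Fp)(Tn+Fn))

Any metric with a zero denominator is reported as 0 and flagged.  The
success rate is the fraction of targets with at least one correct decoy
among their N best-scored decoys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "SuccessRateReport",
    "confusion_counts",
    "compute_metrics",
    "success_rate",
]


@dataclass
class ConfusionCounts:
    """Binary confusion-matrix tallies; correct is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_counts(predicted, gold) -> ConfusionCounts:
    """Tally Tp/Fn/Fp/Tn from aligned boolean vectors (True = correct)."""
    p = np.asarray(predicted, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    if p.shape != g.shape:
        raise ValueError("predicted and gold labels differ in length")
    return ConfusionCounts(
        tp=int((p & g).sum()),
        fn=int((~p & g).sum()),
        fp=int((p & ~g).sum()),
        tn=int((~p & ~g).sum()),
    )


@dataclass
class EvalReport:
    """The eight confusion metrics, with zero-denominator degeneracy flags."""

    p_corr: float
    p_inc: float
    r_corr: float
    r_inc: float
    f1_corr: float
    f1_inc: float
    acc: float
    mcc: float
    degenerate: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "P_corr": self.p_corr,
            "P_inc": self.p_inc,
            "R_corr": self.r_corr,
            "R_inc": self.r_inc,
            "F1_corr": self.f1_corr,
            "F1_inc": self.f1_inc,
            "Acc": self.acc,
            "MCC": self.mcc,
        }


def _ratio(num: float, den: float, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> EvalReport:
    """Evaluate the eight metrics from confusion counts.

    Zero denominators yield 0 for that metric and add its name to the
    ``degenerate`` set (including an MCC denominator of 0 -> MCC 0).
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    flags: set[str] = set()
    p_corr = _ratio(c.tp, c.tp + c.fp, "P_corr", flags)
    p_inc = _ratio(c.tn, c.tn + c.fn, "P_inc", flags)
    r_corr = _ratio(c.tp, c.tp + c.fn, "R_corr", flags)
    r_inc = _ratio(c.tn, c.tn + c.fp, "R_inc", flags)
    f1_corr = _ratio(2 * p_corr * r_corr, p_corr + r_corr, "F1_corr", flags)
    f1_inc = _ratio(2 * p_inc * r_inc, p_inc + r_inc, "F1_inc", flags)
    acc = (c.tp + c.tn) / c.total
    den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, den, "MCC", flags)
    return EvalReport(p_corr, p_inc, r_corr, r_inc, f1_corr, f1_inc, acc, mcc, flags)


@dataclass
class SuccessRateReport:
    """Per-N success rates over targets that have >= 1 correct decoy.

    ``rates`` maps N to the fraction of eligible targets with a correct
    decoy ranked within the top N; ``counts`` the corresponding target
    counts; ``excluded_targets`` lists targets with no correct decoy,
    which are left out of the denominator.
    """

    rates: dict[int, float]
    counts: dict[int, int]
    n_targets: int
    excluded_targets: list = field(default_factory=list)


def success_rate(
    df: pd.DataFrame,
    score_col: str = "score",
    label_col: str = "binary_label",
    n_list=(1, 10, 100),
) -> SuccessRateReport:
    """Top-N success rate of a per-decoy scoring over targets.

    ``df`` needs ``target_id``, ``decoy_id``, a score column (higher =
    more likely correct) and a label column (booleans or
    correct/incorrect strings).  Decoys are ranked per target by
    descending score with ties broken by ascending decoy id; a target
    succeeds at N when at least one gold-correct decoy ranks within the
    top N.  Targets with no correct decoy are excluded from the
    denominator and reported.
    """
    if df.empty:
        raise ValueError("empty input")
    lab = df[label_col]
    if lab.dtype != bool:
        lab = lab.eq("correct")
    work = df.assign(_y=lab.to_numpy())
    n_list = sorted(n_list)
    hits = {n: 0 for n in n_list}
    excluded = []
    n_eligible = 0
    for tid, grp in work.groupby("target_id", sort=True):
        if not grp["_y"].any():
            excluded.append(tid)
            continue
        n_eligible += 1
        ordered = grp.sort_values(
            [score_col, "decoy_id"], ascending=[False, True], kind="mergesort"
        )
        ranks = np.flatnonzero(ordered["_y"].to_numpy())
        best = int(ranks[0]) + 1  # 1-based rank of best correct decoy
        for n in n_list:
            if best <= n:
                hits[n] += 1
    if n_eligible == 0:
        raise ValueError("no target has a correct decoy")
    rates = {n: hits[n] / n_eligible for n in n_list}
    return SuccessRateReport(rates, hits, n_eligible, excluded)
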