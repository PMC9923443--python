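"""Training/validation set assembly: balanced, 3K-unbalanced, silver, augmented.

Docking decoy ensembles are heavily unbalanced (correct poses are a tiny
fraction), so classifiers are trained on per-target balanced subsets; an
unbalanced "3K" variant (3000 decoys per target, at most 600 correct)
serves as a realistic evaluation set.  The silver set is assembled from
per-program rank tables (top-N per program, union with duplicates) and
labeled by the label model; merging it with the gold-labeled core set
yields the augmented training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CORRECT, FeatureTable

__all__ = [
    "DatasetSpec",
    "build_balanced",
    "build_3k",
    "assemble_silver",
    "merge_augmented",
    "composition_stats",
]


@dataclass
class DatasetSpec:
    """Settings for a dataset build."""

    name: str
    cap_correct: int = 600
    total_per_target: int | None = None  # 3000 for 3K sets
    seed: int = 0


def _labels(table: FeatureTable, labels) -> np.ndarray:
    y = table.labels if labels is None else labels
    if y is None:
        raise ValueError("binary labels required")
    return np.asarray(y, dtype=bool)


def build_balanced(
    table: FeatureTable,
    labels=None,
    cap_correct: int = 600,
    seed: int = 0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Per-target balanced set by random undersampling of incorrect decoys.

    For each target: keep min(#correct, cap_correct) correct decoys
    (uniform subsample when over the cap) and an equal-size uniform
    undersample of incorrect decoys, both without replacement.  Targets
    with zero correct decoys are dropped and reported.  Deterministic
    given ``seed``.
    """
    y = _labels(table, labels)
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    rows = []
    for tid, grp in table.df.groupby("target_id", sort=True):
        gy = y[grp.index]
        corr_idx = grp.index[gy].to_numpy()
        inc_idx = grp.index[~gy].to_numpy()
        if len(corr_idx) == 0:
            rows.append((tid, 0, len(inc_idx), 0, 0, "dropped_no_correct"))
            continue
        n = min(len(corr_idx), cap_correct, len(inc_idx))
        note = ""
        if n < min(len(corr_idx), cap_correct):
            note = "short_of_incorrect"
        if len(corr_idx) > n:
            corr_idx = rng.choice(corr_idx, size=n, replace=False)
        inc_pick = rng.choice(inc_idx, size=n, replace=False)
        keep_idx.append(np.sort(np.concatenate([corr_idx, inc_pick])))
        rows.append((tid, len(grp.index[gy]), len(inc_idx), n, n, note))
    report = pd.DataFrame(
        rows,
        columns=[
            "target_id",
            "n_correct_avail",
            "n_incorrect_avail",
            "n_correct_kept",
            "n_incorrect_kept",
            "note",
        ],
    )
    if not keep_idx:
        return table.select(np.zeros(len(table), bool)), report
    mask = np.zeros(len(table), dtype=bool)
    mask[np.concatenate(keep_idx)] = True
    return table.select(mask), report


def build_3k(
    table: FeatureTable,
    labels=None,
    total: int = 3000,
    cap_correct: int = 600,
    seed: int = 0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Per-target unbalanced set: <= cap_correct correct, filled to ``total``.

    For each target keep up to ``cap_correct`` correct decoys (uniform
    subsample when over the cap), then add uniformly sampled incorrect
    decoys until ``total`` decoys in all; if the target has fewer decoys
    than that, take everything and flag insufficiency.
    """
    y = _labels(table, labels)
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    rows = []
    for tid, grp in table.df.groupby("target_id", sort=True):
        gy = y[grp.index]
        corr_idx = grp.index[gy].to_numpy()
        inc_idx = grp.index[~gy].to_numpy()
        n_corr = min(len(corr_idx), cap_correct)
        if len(corr_idx) > n_corr:
            corr_idx = rng.choice(corr_idx, size=n_corr, replace=False)
        n_inc = total - n_corr
        note = ""
        if n_inc > len(inc_idx):
            n_inc = len(inc_idx)
            note = "insufficient_decoys"
            warnings.warn(
                f"target {tid!r}: only {n_corr + n_inc} decoys available "
                f"(requested {total})",
                stacklevel=2,
            )
        inc_pick = (
            rng.choice(inc_idx, size=n_inc, replace=False)
            if n_inc < len(inc_idx)
            else inc_idx
        )
        keep_idx.append(np.sort(np.concatenate([corr_idx, inc_pick])))
        rows.append((tid, n_corr, n_inc, n_corr + n_inc, note))
    report = pd.DataFrame(
        rows, columns=["target_id", "n_correct", "n_incorrect", "n_total", "note"]
    )
    mask = np.zeros(len(table), dtype=bool)
    if keep_idx:
        mask[np.concatenate(keep_idx)] = True
    return table.select(mask), report


@dataclass
class SilverSelection:
    """Outcome of assemble_silver."""

    selected: pd.DataFrame  # target_id, decoy_id, program (with duplicates)
    overlap_report: pd.DataFrame  # per-target pairwise overlap counts
    overlap_total: dict = field(default_factory=dict)


def assemble_silver(
    rank_tables: dict[str, pd.DataFrame],
    n_top: int = 1000,
    overlap_pair: tuple[str, str] | None = None,
    deduplicate: bool = False,
) -> SilverSelection:
    """Select the top-N decoys per target from each program's ranking.

    ``rank_tables`` maps a program name to a DataFrame with ``target_id``
    and ``decoy_id`` columns already sorted by that program's score (best
    first).  The selection is the union-with-duplicates of the per-program
    top slices (set ``deduplicate`` to drop repeats).  The overlap report
    counts decoys shared between each pair of selections per target —
    ``overlap_pair`` names the pair of interest (default: the last two
    programs, matching a native-score vs rescored comparison) — and the
    totals carry both denominators: the per-target slice size ``n_top``
    and the pair's union size.
    """
    if not rank_tables:
        raise ValueError("no rank tables given")
    slices: dict[str, pd.DataFrame] = {}
    for prog, df in rank_tables.items():
        parts = []
        for tid, grp in df.groupby("target_id", sort=True):
            if len(grp) < n_top:
                warnings.warn(
                    f"{prog}/{tid}: ranking has only {len(grp)} decoys "
                    f"(< {n_top})",
                    stacklevel=2,
                )
            parts.append(grp.head(n_top))
        sl = pd.concat(parts, ignore_index=True)[["target_id", "decoy_id"]]
        sl["program"] = prog
        slices[prog] = sl

    progs = list(slices)
    if overlap_pair is None:
        overlap_pair = (progs[-2], progs[-1]) if len(progs) >= 2 else None

    rows = []
    totals: dict = {}
    if overlap_pair is not None:
        a, b = overlap_pair
        sa, sb = slices[a], slices[b]
        shared_total = 0
        union_total = 0
        for tid in sorted(set(sa["target_id"]) | set(sb["target_id"])):
            ia = set(sa.loc[sa["target_id"] == tid, "decoy_id"])
            ib = set(sb.loc[sb["target_id"] == tid, "decoy_id"])
            shared = len(ia & ib)
            union = len(ia | ib)
            shared_total += shared
            union_total += union
            rows.append((tid, a, b, shared, union))
        totals = {
            "pair": overlap_pair,
            "shared": shared_total,
            "overlap_pct_of_top": 100.0 * shared_total / (len(rows) * n_top)
            if rows
            else 0.0,
            "overlap_pct_of_union": 100.0 * shared_total / union_total
            if union_total
            else 0.0,
        }
    report = pd.DataFrame(
        rows, columns=["target_id", "program_a", "program_b", "shared", "union"]
    )
    selected = pd.concat(slices.values(), ignore_index=True)
    if deduplicate:
        selected = selected.drop_duplicates(
            subset=["target_id", "decoy_id"]
        ).reset_index(drop=True)
    return SilverSelection(selected, report, totals)


def merge_augmented(
    core: FeatureTable, silver: FeatureTable
) -> tuple[FeatureTable, dict]:
    """Concatenate the gold-labeled core set with the weak-labeled silver set.

    Both tables must share the same feature schema.  The result carries a
    ``provenance`` column (core/silver) and a ``label_provenance`` column
    (gold/weak); the size report includes the silver correct/incorrect
    counts and the augmented-to-core size ratio.
    """
    if core.feature_names != silver.feature_names:
        raise ValueError("feature schema mismatch between core and silver")
    cdf = core.df.copy()
    sdf = silver.df.copy()
    cdf["provenance"] = "core"
    cdf["label_provenance"] = "gold"
    sdf["provenance"] = "silver"
    sdf["label_provenance"] = "weak"
    merged = pd.concat([cdf, sdf], ignore_index=True)
    out = FeatureTable(merged)
    sy = silver.labels
    n_corr = int(sy.sum()) if sy is not None else 0
    n_inc = int((~sy).sum()) if sy is not None else 0
    report = {
        "n_core": len(core),
        "n_silver": len(silver),
        "n_augmented": len(out),
        "silver_correct": n_corr,
        "silver_incorrect": n_inc,
        "ratio": len(out) / len(core) if len(core) else float("inf"),
    }
    return out, report


def composition_stats(
    n_silver_correct: int,
    n_silver_incorrect: int,
    n_core: int,
    overlap_per_target: float | None = None,
    n_top: int = 1000,
) -> dict:
    """Composition arithmetic for a silver/augmented build.

    From the silver label counts and the core size, derive the silver-set
    correct/incorrect percentages, the augmented-set size and its ratio to
    the core, and (when ``overlap_per_target`` is given, i.e. the mean
    number of decoys shared per target between a program's native and
    rescored top-``n_top`` selections) the selection overlap percentage.
    """
    n_silver = n_silver_correct + n_silver_incorrect
    if n_silver <= 0 or n_core <= 0:
        raise ValueError("counts must be positive")
    stats = {
        "n_silver": n_silver,
        "silver_correct_pct": 100.0 * n_silver_correct / n_silver,
        "silver_incorrect_pct": 100.0 * n_silver_incorrect / n_silver,
        "n_augmented": n_silver + n_core,
        "augmented_over_core": (n_silver + n_core) / n_core,
    }
    if overlap_per_target is not None:
        stats["overlap_pct"] = 100.0 * overlap_per_target / n_top
    return stats
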