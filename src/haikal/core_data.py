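"""Data model, table IO, CAPRI label mapping, clash filtering and normalization.

A decoy table is a flat delimited-text file, one row per docking model
(decoy), with two mandatory id columns (``target_id``, ``decoy_id``),
optional bookkeeping columns (``program``, ``clash_count``, ``capri_class``,
``binary_label``, ``weak_prob``, ``weak_label``, ``covered``,
``provenance``) and any number of numeric feature columns (scoring-function
values).  :class:`FeatureTable` wraps such a table in a pandas DataFrame and
keeps the id/feature split explicit.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CORRECT",
    "INCORRECT",
    "CAPRI_CLASSES",
    "RESERVED_COLUMNS",
    "FeatureTable",
    "NormalizationParams",
    "TableFormatError",
    "capri_to_binary",
    "read_feature_table",
    "write_feature_table",
    "filter_clashes",
    "fit_minmax",
    "apply_minmax",
    "split_by_targets",
]

CORRECT = "correct"
INCORRECT = "incorrect"

#: CAPRI quality classes, in order of increasing quality.
CAPRI_CLASSES = ("I", "A", "M", "H")

#: Columns that are never treated as scoring-function features.
RESERVED_COLUMNS = (
    "target_id",
    "decoy_id",
    "program",
    "clash_count",
    "capri_class",
    "binary_label",
    "weak_prob",
    "weak_label",
    "covered",
    "provenance",
    "label_provenance",
)


class TableFormatError(ValueError):
    """A decoy table violates the expected dialect."""


def capri_to_binary(capri_class: str) -> str:
    """Collapse a CAPRI quality class to a binary correctness label.

    Acceptable, Medium and High quality decoys are ``correct``; Incorrect
    decoys are ``incorrect``.
    """
    if capri_class in ("A", "M", "H"):
        return CORRECT
    if capri_class == "I":
        return INCORRECT
    raise ValueError(f"unknown CAPRI class: {capri_class!r}")


class FeatureTable:
    """A decoy table: id columns plus a numeric feature matrix.

    Parameters
    ----------
    df :
        DataFrame with at least ``target_id`` and ``decoy_id`` columns.
        Every non-reserved column is a feature and must be numeric.
    """

    def __init__(self, df: pd.DataFrame):
        for col in ("target_id", "decoy_id"):
            if col not in df.columns:
                raise TableFormatError(f"missing id column {col!r}")
        dup = df.duplicated(subset=["target_id", "decoy_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["target_id", "decoy_id"]]
            raise TableFormatError(
                f"duplicated (target_id, decoy_id) pair: "
                f"({pair['target_id']!r}, {pair['decoy_id']!r})"
            )
        feats = [c for c in df.columns if c not in RESERVED_COLUMNS]
        for name in feats:
            col = df[name]
            if not pd.api.types.is_numeric_dtype(col):
                bad = col[pd.to_numeric(col, errors="coerce").isna()]
                row = bad.index[0] if len(bad) else "?"
                raise TableFormatError(
                    f"non-numeric value in feature column {name!r} at row {row}"
                )
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise TableFormatError(
                    f"missing value in feature column {name!r} at row {row}"
                )
        self.df = df.reset_index(drop=True)
        self.feature_names: list[str] = feats

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> pd.DataFrame:
        """The decoys x features numeric matrix."""
        return self.df[self.feature_names]

    @property
    def labels(self) -> pd.Series | None:
        """Binary labels as a boolean Series (True = correct), if present.

        Derived from ``binary_label`` when stored, otherwise from
        ``capri_class`` via :func:`capri_to_binary`.
        """
        if "binary_label" in self.df.columns:
            return self.df["binary_label"].eq(CORRECT)
        if "capri_class" in self.df.columns:
            return self.df["capri_class"].map(capri_to_binary).eq(CORRECT)
        return None

    def with_columns(self, **cols) -> "FeatureTable":
        """Return a copy with the given columns assigned."""
        return FeatureTable(self.df.assign(**cols))

    def select(self, mask) -> "FeatureTable":
        """Return the sub-table of rows where ``mask`` holds."""
        return FeatureTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


def read_feature_table(path, sep: str | None = None) -> FeatureTable:
    """Read a delimited decoy table (CSV or TSV, UTF-8, header row).

    The delimiter is inferred from the extension (``.tsv`` -> tab, otherwise
    comma) unless ``sep`` is given.  Labels are parsed when a ``capri_class``
    or ``binary_label`` column is present; row order is preserved.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"target_id": str, "decoy_id": str},
        float_precision="round_trip",
    )
    if "capri_class" in df.columns and "binary_label" not in df.columns:
        df["binary_label"] = df["capri_class"].map(capri_to_binary)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path, sep: str | None = None) -> None:
    """Write a decoy table to delimited text (inverse of read_feature_table)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    # shortest round-trip float form, so write->read is bit-exact
    table.df.to_csv(
        path, sep=sep, index=False, float_format=lambda x: repr(float(x))
    )


@dataclass
class ClashReport:
    """Per-target record of the clash filter."""

    target_id: str
    n_before: int
    n_removed: int
    threshold: float


def filter_clashes(
    table: FeatureTable,
) -> tuple[FeatureTable, list[ClashReport]]:
    """Drop, per target, decoys with unusually many steric clashes.

    A decoy is removed when its clash count strictly exceeds the target's
    mean clash count plus two sample standard deviations (ddof=1).  Targets
    with a single decoy cannot define a standard deviation and are kept
    unfiltered with a warning.
    """
    if "clash_count" not in table.df.columns:
        raise TableFormatError("clash filtering requires a clash_count column")
    if (table.df["clash_count"] < 0).any():
        raise ValueError("clash_count must be nonnegative")
    keep = np.ones(len(table.df), dtype=bool)
    reports: list[ClashReport] = []
    for tid, grp in table.df.groupby("target_id", sort=True):
        counts = grp["clash_count"].to_numpy(dtype=float)
        if len(counts) < 2:
            warnings.warn(
                f"target {tid!r} has a single decoy; clash filter skipped",
                stacklevel=2,
            )
            reports.append(ClashReport(tid, len(counts), 0, np.nan))
            continue
        thr = counts.mean() + 2.0 * counts.std(ddof=1)
        removed = counts > thr  # strict: equality survives
        keep[grp.index[removed]] = False
        reports.append(ClashReport(tid, len(counts), int(removed.sum()), thr))
    return table.select(keep), reports


@dataclass
class NormalizationParams:
    """Per-feature (min, max) learned on the training split.

    Fit once on the training rows and reused unchanged on validation, test
    and silver tables.  Constant (degenerate) features are flagged and map
    to 0 under :func:`apply_minmax`.
    """

    minima: dict[str, float]
    maxima: dict[str, float]
    degenerate: set[str] = field(default_factory=set)

    def __post_init__(self):
        for name in self.minima:
            if self.minima[name] > self.maxima[name]:
                raise ValueError(f"min > max for feature {name!r}")

    def to_text(self) -> str:
        """One feature per line: name<TAB>min<TAB>max<TAB>degenerate-flag."""
        buf = io.StringIO()
        for name in self.minima:
            flag = "degenerate" if name in self.degenerate else "ok"
            buf.write(
                f"{name}\t{self.minima[name]!r}\t{self.maxima[name]!r}\t{flag}\n"
            )
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "NormalizationParams":
        minima, maxima, degen = {}, {}, set()
        for line in text.splitlines():
            if not line.strip():
                continue
            name, lo, hi, flag = line.split("\t")
            minima[name] = float(lo)
            maxima[name] = float(hi)
            if flag == "degenerate":
                degen.add(name)
        return cls(minima, maxima, degen)


def fit_minmax(table: FeatureTable, training_rows) -> NormalizationParams:
    """Learn per-feature min/max over the masked (training) rows only."""
    mask = np.asarray(training_rows, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("training mask selects no rows")
    sub = table.X.loc[mask]
    minima, maxima, degen = {}, {}, set()
    for name in table.feature_names:
        col = sub[name].to_numpy(dtype=float)
        lo, hi = float(col.min()), float(col.max())
        minima[name], maxima[name] = lo, hi
        if lo == hi:
            degen.add(name)
    return NormalizationParams(minima, maxima, degen)


def apply_minmax(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Map each feature value v to (v - min) / (max - min).

    Degenerate features map to 0.  Values outside the training range are
    NOT clipped, so non-training splits may fall outside [0, 1]; tree
    models are insensitive and the information is preserved.
    """
    unknown = [f for f in table.feature_names if f not in params.minima]
    if unknown:
        raise KeyError(f"features without normalization parameters: {unknown}")
    df = table.df.copy()
    for name in table.feature_names:
        if name in params.degenerate:
            df[name] = 0.0
        else:
            lo, hi = params.minima[name], params.maxima[name]
            df[name] = (df[name].astype(float) - lo) / (hi - lo)
    return FeatureTable(df)


def split_by_targets(
    table: FeatureTable, target_ids
) -> tuple[FeatureTable, FeatureTable]:
    """Partition rows by membership of ``target_id`` in ``target_ids``.

    Returns ``(inside, outside)``; the two parts are disjoint and exhaust
    the input.
    """
    ids = set(target_ids)
    mask = table.df["target_id"].isin(ids).to_numpy()
    return table.select(mask), table.select(~mask)
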