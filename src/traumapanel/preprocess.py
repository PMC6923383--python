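"""Cohort pre-processing: complete cases, missingness filter, minimum
imputation, autoscaling and time-point integration.

The canonical order is ``retain_complete_patients`` across time points,
then per time-point table ``filter_missing`` -> ``impute_min`` ->
``autoscale``, then ``integrate_timepoints``.  Everything here is
deterministic.

Two behaviors deserve a note.  The missingness filter removes features
whose missing fraction is *strictly greater* than the threshold, so a
feature missing exactly 70% of entries survives the default filter.
And imputation/scaling are computed on the full table before any
train/test split, which replicates the original procedure but leaks
test-set information into the scaling; :func:`fold_standardize` offers
the leak-free alternative used by the ``refit_preprocessing`` switches
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ALL_TIMEPOINTS, CohortTable

__all__ = [
    "PreprocessReport",
    "retain_complete_patients",
    "filter_missing",
    "impute_min",
    "autoscale",
    "integrate_timepoints",
    "preprocess_table",
    "fold_standardize",
]

DEFAULT_MISSING_THRESHOLD = 0.70


@dataclass
class PreprocessReport:
    """Everything needed to audit or replay a pre-processing pass."""

    dropped_features: dict[str, float] = field(default_factory=dict)
    imputation_values: dict[str, float] = field(default_factory=dict)
    scale_means: dict[str, float] = field(default_factory=dict)
    scale_sds: dict[str, float] = field(default_factory=dict)
    collapsed_duplicates: dict[str, list[str]] = field(default_factory=dict)
    n_patients: int = 0
    notes: list[str] = field(default_factory=list)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            dropped_features={**self.dropped_features, **other.dropped_features},
            imputation_values={**self.imputation_values, **other.imputation_values},
            scale_means={**self.scale_means, **other.scale_means},
            scale_sds={**self.scale_sds, **other.scale_sds},
            collapsed_duplicates={**self.collapsed_duplicates, **other.collapsed_duplicates},
            n_patients=other.n_patients or self.n_patients,
            notes=self.notes + other.notes,
        )

    def to_dict(self) -> dict:
        return {
            "dropped_features": self.dropped_features,
            "imputation_values": self.imputation_values,
            "scale_means": self.scale_means,
            "scale_sds": self.scale_sds,
            "collapsed_duplicates": self.collapsed_duplicates,
            "n_patients": self.n_patients,
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def retain_complete_patients(tables: list[CohortTable]) -> list[CohortTable]:
    """Keep only patients present (with outcome) in every table.

    Output tables share the retained patients in the order of the first
    table's index.
    """
    if not tables:
        raise ValueError("need at least one table")
    keep = tables[0].data.index
    for t in tables[1:]:
        keep = keep.intersection(t.data.index, sort=False)
    keep = [p for p in tables[0].data.index if p in set(keep)]
    if not keep:
        raise ValueError("no patient is present in all time-point tables")
    return [t.subset_patients(keep) for t in tables]


def filter_missing(
    table: CohortTable, threshold: float = DEFAULT_MISSING_THRESHOLD
) -> tuple[CohortTable, PreprocessReport]:
    """Drop features whose missing fraction strictly exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0,1], got {threshold}")
    frac = table.data.isna().mean()
    dropped = frac.index[frac > threshold].tolist()
    if len(dropped) == table.n_features:
        raise ValueError("missingness filter removed every feature")
    report = PreprocessReport(
        dropped_features={f: float(frac[f]) for f in dropped},
        n_patients=table.n_patients,
    )
    kept = [f for f in table.data.columns if f not in set(dropped)]
    return table.subset_features(kept), report


def impute_min(table: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Replace each missing entry by the feature's observed minimum."""
    all_missing = table.data.columns[table.data.isna().all()].tolist()
    if all_missing:
        raise ValueError(
            f"features with no observed values (filter first): {all_missing}"
        )
    mins = table.data.min(skipna=True)
    out = table.copy()
    imputed = {}
    for f in out.data.columns:
        if out.data[f].isna().any():
            out.data[f] = out.data[f].fillna(mins[f])
            imputed[f] = float(mins[f])
    report = PreprocessReport(imputation_values=imputed, n_patients=table.n_patients)
    return out, report


def autoscale(table: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Standardize each feature to mean 0, sample SD 1 (denominator n-1)."""
    if table.data.isna().any().any():
        raise ValueError("autoscale requires a fully observed table; impute first")
    means = table.data.mean()
    sds = table.data.std(ddof=1)
    dead = sds.index[~(sds > 1e-12)].tolist()
    if dead:
        raise ValueError(f"zero-variance features cannot be autoscaled: {dead}")
    out = table.copy()
    out.data = (out.data - means) / sds
    report = PreprocessReport(
        scale_means={f: float(means[f]) for f in table.data.columns},
        scale_sds={f: float(sds[f]) for f in table.data.columns},
        n_patients=table.n_patients,
    )
    return out, report


def preprocess_table(
    table: CohortTable, threshold: float = DEFAULT_MISSING_THRESHOLD
) -> tuple[CohortTable, PreprocessReport]:
    """Canonical filter -> impute -> autoscale pipeline for one table."""
    t, r1 = filter_missing(table, threshold)
    t, r2 = impute_min(t)
    t, r3 = autoscale(t)
    return t, r1.merge(r2).merge(r3)


def integrate_timepoints(tables: list[CohortTable]) -> tuple[CohortTable, PreprocessReport]:
    """Concatenate per-time-point tables into one wide matrix.

    Clinical-score columns repeated across time points (same name, same
    values) collapse to a single column tagged for all time points; a
    same-named clinical column with diverging values is an error.  With
    the study shape (68+68+67 columns, 3 clinical scores shared by all
    three tables) this yields the 197-column integrated matrix.
    """
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    for t in tables[1:]:
        if not t.data.index.equals(first.data.index):
            raise ValueError("patient order differs between time-point tables")
        if not t.outcome.equals(first.outcome):
            raise ValueError("outcome differs between time-point tables")
    if len(tables) == 1:
        return first.copy(), PreprocessReport(n_patients=first.n_patients)

    report = PreprocessReport(n_patients=first.n_patients)
    data_cols: dict[str, pd.Series] = {}
    meta_rows: dict[str, tuple[str, str]] = {}
    collapsed: dict[str, list[str]] = {}
    for t in tables:
        for f in t.data.columns:
            role = t.feature_meta.loc[f, "role"]
            tp = t.feature_meta.loc[f, "timepoint"]
            if f in data_cols:
                if role == "clinical":
                    if not np.array_equal(
                        data_cols[f].to_numpy(), t.data[f].to_numpy()
                    ):
                        raise ValueError(
                            f"clinical column {f!r} repeats across time points "
                            "with different values"
                        )
                    collapsed.setdefault(f, [meta_rows[f][0]]).append(tp)
                    meta_rows[f] = (ALL_TIMEPOINTS, "clinical")
                    continue
                raise ValueError(f"duplicate non-clinical feature name {f!r}")
            data_cols[f] = t.data[f]
            meta_rows[f] = (tp, role)
    if collapsed:
        report.collapsed_duplicates = collapsed
        report.notes.append(
            f"collapsed {sum(len(v) - 1 for v in collapsed.values())} duplicated "
            f"clinical-score columns: {sorted(collapsed)}"
        )
    data = pd.DataFrame(data_cols, index=first.data.index)
    meta = pd.DataFrame(
        {
            "timepoint": [meta_rows[f][0] for f in data.columns],
            "role": [meta_rows[f][1] for f in data.columns],
        },
        index=data.columns,
    )
    return CohortTable(data, first.outcome.copy(), meta), report


def fold_standardize(
    X_train: np.ndarray, X_test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Impute (train minima) and autoscale (train mean/SD) inside a fold.

    The leak-free counterpart of the global pipeline: all statistics come
    from the training rows and are applied unchanged to the test rows.
    """
    Xtr = np.array(X_train, dtype=float, copy=True)
    mins = np.nanmin(Xtr, axis=0)
    inds = np.where(np.isnan(Xtr))
    Xtr[inds] = np.take(mins, inds[1])
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0  # degenerate-in-fold features carry no information
    Xtr = (Xtr - mean) / sd
    if X_test is None:
        return np.ascontiguousarray(Xtr), None
    Xte = np.array(X_test, dtype=float, copy=True)
    inds = np.where(np.isnan(Xte))
    Xte[inds] = np.take(mins, inds[1])
    Xte = (Xte - mean) / sd
    return np.ascontiguousarray(Xtr), np.ascontiguousarray(Xte)
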