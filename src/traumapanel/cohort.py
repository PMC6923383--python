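"""Patient-by-feature cohort container.

A :class:`CohortTable` bundles the numeric feature matrix (missing entries
allowed), the binary outcome vector and per-feature metadata (time-point
tag and role).  Feature roles distinguish immune readouts from clinical
severity scores (NISS, PS14, ...), which the pipeline treats specially:
clinical scores are excluded from stability selection by default and
appended to candidate panels during evaluation.

On disk a cohort is a plain CSV (patients as rows, first column the
patient identifier, outcome column ``MODS``, feature columns suffixed by
time point, e.g. ``_t1``) plus a small JSON sidecar carrying the feature
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

OUTCOME_COLUMN = "MODS"
#: time-point tag for features shared across all time points (clinical scores)
ALL_TIMEPOINTS = "all"

ROLES = ("immune", "clinical", "other")


@dataclass
class CohortTable:
    """Numeric cohort with outcome and per-feature metadata.

    Parameters
    ----------
    data
        Feature matrix, patients as rows (index = patient identifiers).
    outcome
        Binary outcome (0/1) aligned with ``data.index``.
    feature_meta
        One row per feature (index = feature name) with columns
        ``timepoint`` and ``role`` (one of :data:`ROLES`).
    """

    data: pd.DataFrame
    outcome: pd.Series
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"timepoint": ALL_TIMEPOINTS, "role": "immune"},
                index=self.data.columns,
            )
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if not self.outcome.index.equals(self.data.index):
            raise ValueError("outcome index does not match patient index")
        vals = self.outcome.dropna().unique()
        if not set(vals) <= {0, 1}:
            raise ValueError(f"outcome must be binary 0/1, got {sorted(vals)}")
        if self.outcome.isna().any():
            missing = self.outcome.index[self.outcome.isna()].tolist()
            raise ValueError(f"outcome missing for patients {missing}")
        if not self.feature_meta.index.equals(self.data.columns):
            raise ValueError("feature_meta index does not match feature columns")
        bad = set(self.feature_meta["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown feature roles: {sorted(bad)}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def timepoints(self) -> list[str]:
        tps = [t for t in self.feature_meta["timepoint"].unique() if t != ALL_TIMEPOINTS]
        return sorted(tps)

    def features(self, role: str | None = None, timepoint: str | None = None) -> list[str]:
        """Feature names filtered by role and/or time point."""
        meta = self.feature_meta
        mask = pd.Series(True, index=meta.index)
        if role is not None:
            mask &= meta["role"] == role
        if timepoint is not None:
            mask &= meta["timepoint"].isin([timepoint, ALL_TIMEPOINTS])
        return meta.index[mask].tolist()

    def subset_features(self, names: list[str]) -> "CohortTable":
        return CohortTable(
            data=self.data[names].copy(),
            outcome=self.outcome.copy(),
            feature_meta=self.feature_meta.loc[names].copy(),
        )

    def subset_patients(self, patients) -> "CohortTable":
        return CohortTable(
            data=self.data.loc[patients].copy(),
            outcome=self.outcome.loc[patients].copy(),
            feature_meta=self.feature_meta.copy(),
        )

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.outcome.copy(), self.feature_meta.copy())

    def matrix(self, features: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) as C-contiguous float64 arrays for the solvers."""
        cols = features if features is not None else list(self.data.columns)
        X = np.ascontiguousarray(self.data[cols].to_numpy(dtype=np.float64))
        y = self.outcome.to_numpy(dtype=np.float64)
        return X, y

    def split_by_timepoint(self) -> list["CohortTable"]:
        """Per-time-point sub-cohorts; ``all``-tagged features (clinical
        scores) are replicated into every table."""
        shared = self.feature_meta.index[
            self.feature_meta["timepoint"] == ALL_TIMEPOINTS
        ].tolist()
        out = []
        for tp in self.timepoints:
            own = self.feature_meta.index[self.feature_meta["timepoint"] == tp].tolist()
            cols = own + shared
            meta = self.feature_meta.loc[cols].copy()
            meta.loc[shared, "timepoint"] = tp
            out.append(CohortTable(self.data[cols].copy(), self.outcome.copy(), meta))
        return out

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path, patient_col: str = "patient_id") -> None:
        """Write the cohort CSV plus a ``<stem>.meta.json`` sidecar."""
        path = Path(path)
        df = self.data.copy()
        df.insert(0, OUTCOME_COLUMN, self.outcome.astype(int))
        df.index.name = patient_col
        df.to_csv(path)
        sidecar = path.with_suffix(".meta.json")
        meta = {
            "timepoint": self.feature_meta["timepoint"].to_dict(),
            "role": self.feature_meta["role"].to_dict(),
        }
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        clinical_columns: list[str] | None = None,
        timepoint_labels: list[str] | None = None,
    ) -> "CohortTable":
        """Read a cohort CSV.

        If the ``.meta.json`` sidecar exists it provides the feature
        metadata; otherwise time points are inferred from ``_<label>``
        suffixes and roles from ``clinical_columns``.
        """
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        if OUTCOME_COLUMN not in df.columns:
            raise ValueError(f"outcome column {OUTCOME_COLUMN!r} not found in {path}")
        outcome = df[OUTCOME_COLUMN]
        data = df.drop(columns=[OUTCOME_COLUMN])
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fm = pd.DataFrame(
                {
                    "timepoint": pd.Series(meta["timepoint"]),
                    "role": pd.Series(meta["role"]),
                }
            ).loc[data.columns]
        else:
            clinical = set(clinical_columns or [])
            labels = timepoint_labels
            tps, roles = [], []
            for c in data.columns:
                tp = ALL_TIMEPOINTS
                if "_" in c:
                    suffix = c.rsplit("_", 1)[1]
                    if labels is None or suffix in labels:
                        tp = suffix
                tps.append(ALL_TIMEPOINTS if c in clinical else tp)
                roles.append("clinical" if c in clinical else "immune")
            fm = pd.DataFrame({"timepoint": tps, "role": roles}, index=data.columns)
        return cls(data=data, outcome=outcome, feature_meta=fm)
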