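"""Dual LASSO / elastic-net stability selection.

The selector repeats, ``n_iterations`` times (default 100): draw a
random stratified 75/25 patient split, tune the penalty strength on the
training portion by 10-fold cross-validation, refit at the tuned
penalty, and record which features carry nonzero coefficients.  This is
done independently for each mixing parameter (default LASSO ``alpha=1``
and elastic net ``alpha=0.5``).  Per-feature appearance frequencies are
then thresholded at an upper quantile of the frequency distribution
(default the 75th percentile; a stricter level is used for integrated
multi-time-point analyses), and the per-alpha selections are combined
(union by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .penalized import cv_lambda_index, fit_path, lambda_grid
from .preprocess import fold_standardize

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "upper_quantile_threshold",
    "stability_select",
]

log = logging.getLogger(__name__)

#: quantile level of the stricter preset used for integrated analyses
STRINGENT_LEVEL = 0.90


@dataclass
class SelectionConfig:
    n_iterations: int = 100
    train_fraction: float = 0.75
    cv_folds: int = 10
    alphas: tuple[float, ...] = (1.0, 0.5)
    threshold_level: float = 0.75
    combine_rule: str = "union"
    stratified: bool = True
    cv_metric: str = "deviance"
    refit_preprocessing: bool = False
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must lie in (0,1), got {self.train_fraction}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for a in self.alphas:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha must lie in [0,1], got {a}")
        if not 0.0 < self.threshold_level < 1.0:
            raise ValueError("threshold_level must lie in (0,1)")
        if self.combine_rule not in ("union", "intersection"):
            raise ValueError(f"combine_rule must be union|intersection, got {self.combine_rule!r}")

    def stringent(self) -> "SelectionConfig":
        """The stricter preset for integrated analyses."""
        import dataclasses

        return dataclasses.replace(self, threshold_level=STRINGENT_LEVEL)


@dataclass
class SelectionResult:
    """Appearance frequencies, per-iteration coefficients and selections."""

    n_iterations: int
    features: list[str]
    #: per-alpha counts of iterations with a nonzero coefficient
    frequencies: dict[float, pd.Series]
    #: per-alpha long-format records (iteration, feature, coef, lambda)
    coefficients: dict[float, pd.DataFrame]
    thresholds: dict[float, float]
    selected: dict[float, list[str]]
    combined: list[str]
    combine_rule: str
    n_redraws: int = 0

    def frequency_table(self) -> pd.DataFrame:
        """Wide table of frequencies, one column per alpha."""
        return pd.DataFrame({f"alpha_{a:g}": s for a, s in self.frequencies.items()})

    def to_json(self, path: str | Path) -> None:
        out = {
            "n_iterations": self.n_iterations,
            "combine_rule": self.combine_rule,
            "n_redraws": self.n_redraws,
            "thresholds": {f"{a:g}": v for a, v in self.thresholds.items()},
            "selected": {f"{a:g}": s for a, s in self.selected.items()},
            "combined": self.combined,
            "frequencies": {
                f"{a:g}": {k: int(v) for k, v in s.items()} for a, s in self.frequencies.items()
            },
        }
        Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))

    def write_csvs(self, directory: str | Path, prefix: str = "selection") -> list[Path]:
        """Frequency table and long-format coefficient records."""
        directory = Path(directory)
        paths = []
        p = directory / f"{prefix}_frequencies.csv"
        self.frequency_table().rename_axis("feature").to_csv(p)
        paths.append(p)
        for a, df in self.coefficients.items():
            q = directory / f"{prefix}_coefficients_alpha{a:g}.csv"
            df.to_csv(q, index=False)
            paths.append(q)
        return paths


def upper_quantile_threshold(
    frequencies: pd.Series | np.ndarray, level: float = 0.75
) -> tuple[float, list[str]]:
    """Empirical quantile of the frequency vector and the features
    strictly above it.

    Zeros count: the quantile is taken over *all* features, so in a
    sparse frequency vector the threshold sits low and any repeatedly
    chosen feature clears it, while a flat vector selects nothing.
    Linear interpolation (numpy default) is used between order
    statistics.
    """
    if isinstance(frequencies, pd.Series):
        names = list(frequencies.index)
        values = frequencies.to_numpy(dtype=float)
    else:
        values = np.asarray(frequencies, dtype=float)
        names = [str(i) for i in range(len(values))]
    if len(values) == 0:
        raise ValueError("empty frequency vector")
    if (values < 0).any():
        raise ValueError("frequencies must be nonnegative")
    thr = float(np.quantile(values, level))
    selected = [n for n, v in zip(names, values) if v > thr]
    return thr, selected


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    tr, te = [], []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_tr = min(max(int(round(train_fraction * len(idx))), 1), len(idx) - 1)
        tr.append(idx[:n_tr])
        te.append(idx[n_tr:])
    return np.concatenate(tr), np.concatenate(te)


def stability_select(table: CohortTable, config: SelectionConfig) -> SelectionResult:
    """Run the repeated-subsampling selector on a preprocessed table.

    Every feature column of ``table`` enters the design matrix; the
    caller decides what to include (the pipeline passes immune features
    only by default).  Same table + config => identical result.
    """
    config.validate()
    features = list(table.data.columns)
    if not features:
        raise ValueError("table has no features")
    X_all = table.data.to_numpy(dtype=float)
    y_all = table.outcome.to_numpy(dtype=float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("outcome contains a single class")

    ss = np.random.SeedSequence(config.seed)
    counts = {a: np.zeros(len(features), dtype=int) for a in config.alphas}
    records: dict[float, list[dict]] = {a: [] for a in config.alphas}
    n_redraws = 0
    max_attempts = 5 * config.n_iterations
    it = 0
    attempt = 0
    while it < config.n_iterations:
        if attempt >= max_attempts:
            raise RuntimeError(
                f"exceeded {max_attempts} split attempts after {it} completed iterations"
            )
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        iter_seed = int(rng.integers(2**31 - 1))
        attempt += 1
        if config.stratified:
            tr, _ = _stratified_split(y_all, config.train_fraction, rng)
        else:
            idx = rng.permutation(len(y_all))
            n_tr = int(round(config.train_fraction * len(y_all)))
            tr = idx[:n_tr]
            if len(np.unique(y_all[tr])) < 2:
                n_redraws += 1
                log.info("iteration redrawn: single-class training split")
                continue
        Xtr = np.ascontiguousarray(X_all[tr])
        ytr = y_all[tr]
        if config.refit_preprocessing:
            Xtr, _ = fold_standardize(Xtr)
        try:
            for a in config.alphas:
                grid = lambda_grid(
                    Xtr, ytr, a, n_lambda=config.n_lambda, min_ratio=config.lambda_min_ratio
                )
                idx = cv_lambda_index(
                    Xtr,
                    ytr,
                    a,
                    grid,
                    cv_folds=config.cv_folds,
                    seed=iter_seed,
                    metric=config.cv_metric,
                    stratified=config.stratified,
                )
                lam = float(grid[idx])
                # refit on the full training split along the (warm-started)
                # path, descending only as far as the tuned lambda, and read
                # off the solution there
                B, _ = fit_path(Xtr, ytr, a, grid[: idx + 1], tol=1e-7)
                coef = B[idx]
                nz = np.flatnonzero(coef)
                counts[a][nz] += 1
                for j in nz:
                    records[a].append(
                        {
                            "iteration": it,
                            "feature": features[j],
                            "coef": float(coef[j]),
                            "lambda": lam,
                        }
                    )
        except ValueError as exc:
            n_redraws += 1
            log.info("iteration redrawn after fit error: %s", exc)
            continue
        it += 1

    frequencies = {a: pd.Series(counts[a], index=features) for a in config.alphas}
    thresholds: dict[float, float] = {}
    selected: dict[float, list[str]] = {}
    for a in config.alphas:
        thr, sel = upper_quantile_threshold(frequencies[a], config.threshold_level)
        thresholds[a] = thr
        selected[a] = sel
    sets = [set(s) for s in selected.values()]
    if config.combine_rule == "union":
        combined_set = set().union(*sets)
    else:
        combined_set = set.intersection(*sets) if sets else set()
    combined = [f for f in features if f in combined_set]
    coefficients = {
        a: pd.DataFrame(records[a], columns=["iteration", "feature", "coef", "lambda"])
        for a in config.alphas
    }
    return SelectionResult(
        n_iterations=config.n_iterations,
        features=features,
        frequencies=frequencies,
        coefficients=coefficients,
        thresholds=thresholds,
        selected=selected,
        combined=combined,
        combine_rule=config.combine_rule,
        n_redraws=n_redraws,
    )
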