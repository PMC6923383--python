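"""Panel evaluation: repeated-split GLM AUC distributions against a
label-permutation null.

A candidate marker panel (selected once, upstream) is scored by fitting
an unpenalized binomial GLM on repeated stratified 65/35 train/test
splits and collecting the test ROC AUC of each split; the same machinery
run on freshly permuted outcome labels gives the null distribution.  The
permutation p-value is the fraction of permuted AUCs above the mean real
AUC, and the confidence interval is the empirical percentile interval of
the real AUC sample.

AUC is the Mann-Whitney statistic (ties get half credit), so any
strictly increasing transform of the scores leaves it unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .preprocess import fold_standardize

__all__ = [
    "EvalConfig",
    "EvalResult",
    "FittedGLM",
    "fit_glm",
    "score_auc",
    "resampled_auc",
    "nested_panel_auc",
    "permutation_pvalue",
    "evaluate_panel",
    "univariate_panel",
    "improvement_pp",
    "timepoint_group_test",
]


@dataclass
class EvalConfig:
    n_resamples: int = 1000
    train_fraction: float = 0.65
    n_permutation_resamples: int = 1000
    ci_level: float = 0.95
    stratified: bool = True
    refit_preprocessing: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must lie in (0,1), got {self.train_fraction}")
        if self.n_resamples < 1 or self.n_permutation_resamples < 1:
            raise ValueError("resample counts must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must lie in (0,1), got {self.ci_level}")


class FittedGLM(NamedTuple):
    """Unpenalized (or ridge-stabilized) binomial GLM fit."""

    coef: np.ndarray
    intercept: float
    used_ridge: bool

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor (monotone in predicted risk)."""
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 50, tol: float = 1e-10):
    """Newton/IRLS for binomial log-likelihood with optional L2 on slopes."""
    n, p = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = Z.T @ (y - mu) - pen * beta
        H = (Z * w[:, None]).T @ Z + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    return beta, converged


def fit_glm(X_train: np.ndarray, y_train: np.ndarray, ridge: float = 1e-4) -> FittedGLM:
    """Fit an unpenalized binomial GLM; stabilize on (near-)separation.

    If the unpenalized Newton iteration fails to converge or the
    coefficients run away (the signature of perfect separation at these
    sample sizes), the fit is redone with a tiny L2 penalty ``ridge`` on
    the slopes, which leaves the score ordering intact.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim == 1:
        X_train = X_train[:, None]
    y_train = np.asarray(y_train, dtype=float)
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("y_train contains a single class")
    if X_train.shape[1] == 0:
        # intercept-only model: constant scores
        p = y_train.mean()
        return FittedGLM(np.zeros(0), float(np.log(p / (1 - p))), False)
    beta, converged = _irls(X_train, y_train, ridge=0.0, max_iter=30)
    if not converged or np.abs(beta).max() > 1e3:
        beta, _ = _irls(X_train, y_train, ridge=ridge, max_iter=60)
        return FittedGLM(beta[1:], float(beta[0]), True)
    return FittedGLM(beta[1:], float(beta[0]), False)


def score_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney statistic with half credit for ties.

    Equals ``(#{pos>neg} + 0.5*#{pos=neg}) / (n_pos*n_neg)`` over all
    positive/negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels contain a single class")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """Index split preserving class balance; both classes land on both sides."""
    train_idx = []
    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train_idx.append(idx[:n_tr])
        test_idx.append(idx[n_tr:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _plain_split(n: int, train_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_tr = int(round(train_fraction * n))
    return idx[:n_tr], idx[n_tr:]


def resampled_auc(
    table: CohortTable,
    features: list[str],
    config: EvalConfig,
    permute: bool = False,
    n_resamples: int | None = None,
) -> np.ndarray:
    """Test-set AUCs over repeated train/test splits.

    With ``permute=True`` the outcome labels are freshly permuted before
    every resample, yielding the null distribution of the same pipeline.
    Splits are stratified by (possibly permuted) outcome by default.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    X = table.data[features].to_numpy(dtype=float)
    y = table.outcome.to_numpy(dtype=float)
    n = len(y)
    n_out = n_resamples if n_resamples is not None else (
        config.n_permutation_resamples if permute else config.n_resamples
    )
    stream = np.random.default_rng(
        np.random.SeedSequence((config.seed, 1 if permute else 0))
    )
    aucs = np.empty(n_out)
    attempts = 0
    i = 0
    while i < n_out:
        if attempts > 20 * n_out:
            raise RuntimeError("too many degenerate resamples; check the data")
        attempts += 1
        yy = stream.permutation(y) if permute else y
        if config.stratified:
            tr, te = _stratified_split(yy, config.train_fraction, stream)
        else:
            tr, te = _plain_split(n, config.train_fraction, stream)
            if len(np.unique(yy[tr])) < 2 or len(np.unique(yy[te])) < 2:
                continue  # redraw: split lost a class
        Xtr, Xte = X[tr], X[te]
        if config.refit_preprocessing:
            Xtr, Xte = fold_standardize(Xtr, Xte)
        model = fit_glm(Xtr, yy[tr])
        aucs[i] = score_auc(model.decision(Xte), yy[te])
        i += 1
    return aucs


def nested_panel_auc(
    table: CohortTable,
    selection_config,
    config: EvalConfig,
    n_resamples: int | None = None,
) -> tuple[np.ndarray, list[list[str]]]:
    """Fully nested evaluation: re-select the panel inside every resample.

    The default two-stage design selects once on all patients and only
    re-fits the GLM per split, which is optimistic because selection has
    seen the test patients.  Here each resample re-runs stability
    selection on its training portion alone before scoring the held-out
    patients, at a considerable computational cost.  A resample whose
    selection comes back empty is scored by the intercept-only model
    (constant scores, AUC 1/2).  Returns the AUC sample and the panel
    chosen in each resample.
    """
    import dataclasses

    from .selection import stability_select  # local import: avoids a module cycle

    config.validate()
    n_out = n_resamples if n_resamples is not None else config.n_resamples
    y = table.outcome.to_numpy(dtype=float)
    ss = np.random.SeedSequence((config.seed, 2))
    stream = np.random.default_rng(ss)
    aucs = np.empty(n_out)
    panels: list[list[str]] = []
    for i in range(n_out):
        tr, te = _stratified_split(y, config.train_fraction, stream)
        sub = table.subset_patients(table.data.index[tr])
        sel_seed = int(stream.integers(2**31 - 1))
        sel = stability_select(
            sub, dataclasses.replace(selection_config, seed=sel_seed)
        )
        panel = sel.combined
        panels.append(panel)
        Xtr = table.data[panel].to_numpy(dtype=float)[tr] if panel else np.empty((len(tr), 0))
        Xte = table.data[panel].to_numpy(dtype=float)[te] if panel else np.empty((len(te), 0))
        model = fit_glm(Xtr, y[tr])
        aucs[i] = score_auc(model.decision(Xte), y[te])
    return aucs, panels


class PermutationP(NamedTuple):
    p_value: float
    p_value_corrected: float


def permutation_pvalue(real_aucs: np.ndarray, permuted_aucs: np.ndarray) -> PermutationP:
    """Fraction of permuted AUCs above the mean real AUC.

    The bias-corrected variant ``(k+1)/(n+1)`` never returns exactly 0
    and is reported alongside.
    """
    real_aucs = np.asarray(real_aucs, dtype=float)
    permuted_aucs = np.asarray(permuted_aucs, dtype=float)
    if len(real_aucs) == 0 or len(permuted_aucs) == 0:
        raise ValueError("need nonempty real and permuted AUC samples")
    ref = real_aucs.mean()
    k = int((permuted_aucs > ref).sum())
    n = len(permuted_aucs)
    return PermutationP(k / n, (k + 1) / (n + 1))


@dataclass
class EvalResult:
    """Real and permuted AUC samples for one panel, with summaries."""

    features: list[str]
    real_aucs: np.ndarray
    permuted_aucs: np.ndarray
    real_mean: float = 0.0
    real_sd: float = 0.0
    permuted_mean: float = 0.0
    permuted_sd: float = 0.0
    ci: tuple[float, float] = (0.0, 1.0)
    p_value: float = 1.0
    p_value_corrected: float = 1.0
    notes: list[str] = field(default_factory=list)

    @classmethod
    def from_samples(
        cls,
        features: list[str],
        real_aucs: np.ndarray,
        permuted_aucs: np.ndarray,
        ci_level: float = 0.95,
    ) -> "EvalResult":
        pp = permutation_pvalue(real_aucs, permuted_aucs)
        lo = (1.0 - ci_level) / 2.0
        return cls(
            features=list(features),
            real_aucs=np.asarray(real_aucs, dtype=float),
            permuted_aucs=np.asarray(permuted_aucs, dtype=float),
            real_mean=float(np.mean(real_aucs)),
            real_sd=float(np.std(real_aucs, ddof=1)) if len(real_aucs) > 1 else 0.0,
            permuted_mean=float(np.mean(permuted_aucs)),
            permuted_sd=float(np.std(permuted_aucs, ddof=1)) if len(permuted_aucs) > 1 else 0.0,
            ci=(
                float(np.quantile(real_aucs, lo)),
                float(np.quantile(real_aucs, 1.0 - lo)),
            ),
            p_value=pp.p_value,
            p_value_corrected=pp.p_value_corrected,
        )

    def summary(self) -> dict:
        return {
            "features": self.features,
            "real_auc_mean": self.real_mean,
            "real_auc_sd": self.real_sd,
            "permuted_auc_mean": self.permuted_mean,
            "permuted_auc_sd": self.permuted_sd,
            "ci": list(self.ci),
            "p_value": self.p_value,
            "p_value_corrected": self.p_value_corrected,
            "n_resamples": len(self.real_aucs),
            "n_permutation_resamples": len(self.permuted_aucs),
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        out = self.summary()
        out["real_aucs"] = [round(float(v), 10) for v in self.real_aucs]
        out["permuted_aucs"] = [round(float(v), 10) for v in self.permuted_aucs]
        Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


def evaluate_panel(table: CohortTable, features: list[str], config: EvalConfig) -> EvalResult:
    """Real + permuted resampled AUCs and their summaries for one panel."""
    real = resampled_auc(table, features, config, permute=False)
    perm = resampled_auc(table, features, config, permute=True)
    return EvalResult.from_samples(features, real, perm, ci_level=config.ci_level)


def univariate_panel(
    table: CohortTable, features: list[str], config: EvalConfig
) -> tuple[list[EvalResult], EvalResult, pd.DataFrame]:
    """Per-feature univariate results, the multivariate result, and the
    dumbbell-plot table (feature, mean real AUC, mean permuted AUC)."""
    if not features:
        raise ValueError("need at least one feature")
    uni = [evaluate_panel(table, [f], config) for f in features]
    multi = evaluate_panel(table, features, config)
    rows = [
        {"feature": f, "real_auc_mean": r.real_mean, "permuted_auc_mean": r.permuted_mean}
        for f, r in zip(features, uni)
    ]
    rows.append(
        {
            "feature": "Multivariate",
            "real_auc_mean": multi.real_mean,
            "permuted_auc_mean": multi.permuted_mean,
        }
    )
    return uni, multi, pd.DataFrame(rows)


def improvement_pp(multivariate: EvalResult, univariate: EvalResult) -> float:
    """Mean-AUC improvement of the panel over a single reference feature,
    in percentage points (the scale on which '8% over PS14' is quoted)."""
    return 100.0 * (multivariate.real_mean - univariate.real_mean)


def timepoint_group_test(
    values_by_group: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Pairwise Welch two-sample t-tests between named groups.

    Intended for comparing a marker's raw values between time points (or
    between outcome groups).  Degenerate comparisons (fewer than two
    observations, or zero variance in both groups) yield NaN rather than
    raising.
    """
    names = list(values_by_group)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = np.asarray(values_by_group[a], dtype=float)
            vb = np.asarray(values_by_group[b], dtype=float)
            va = va[~np.isnan(va)]
            vb = vb[~np.isnan(vb)]
            if len(va) < 2 or len(vb) < 2 or (va.std() == 0 and vb.std() == 0):
                if len(va) >= 2 and len(vb) >= 2 and np.array_equal(np.sort(va), np.sort(vb)):
                    p = 1.0  # identical degenerate samples: no evidence of difference
                else:
                    p = np.nan
            else:
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
            rows.append({"group_a": a, "group_b": b, "p_value": p})
    return pd.DataFrame(rows)
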