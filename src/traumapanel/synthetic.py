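"""Seeded synthetic trauma cohorts with known ground truth.

The generator emulates the statistical shape of an early post-trauma
immune-profiling study: ~61 patients followed at three time points
(<=1 h, 4-12 h, 48-72 h) with ~68 numeric features per time point, a
binary multi-organ-dysfunction outcome at 30-40% prevalence, a handful
of genuinely informative markers, clinical severity scores (NISS, PS14,
ISS) that are themselves predictive, correlated blocks of noise
features, and per-feature missingness including features bad enough to
trip the 70% removal filter.

Features are group-conditional Gaussians: a feature with planted effect
size ``d`` is N(0,1) in the non-event group and N(d,1) in the event
group, so ``d`` is the standardized mean difference and the univariate
ROC AUC of a planted feature is ``Phi(d/sqrt(2))``.  Everything is
reproducible from the spec's single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ALL_TIMEPOINTS, CohortTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort", "inject_missingness", "study_spec"]

#: defaults mirroring the study design this generator emulates
STUDY_TIMEPOINTS = ("t1", "t2", "t3")
STUDY_FEATURES_PER_TP = (68, 68, 67)
# clinical-score separations chosen so the univariate AUC Phi(d/sqrt(2))
# lands near the reported discriminative ability of each score
# (NISS ~0.72, PS14 ~0.84, ISS a little below NISS)
STUDY_CLINICAL = (("NISS", 0.82), ("PS14", 1.40), ("ISS", 0.70))
STUDY_MARKERS = (("t1", 1.5), ("t3", 1.5), ("t3", 1.5))


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``n_features_per_timepoint`` counts the full width of each per-time-
    point table, clinical scores included (clinical scores are generated
    once and shared across time points).  ``planted_markers`` is a list
    of ``(timepoint, d)`` pairs; ``clinical_scores`` of ``(name, d)``
    pairs, with ``d`` the standardized mean difference between outcome
    groups.  ``missing_rates`` maps feature names to MCAR masking
    probabilities; features not listed default to 0.  When it is None, a
    study-like default is applied at injection time: 0.05 on every
    immune feature and 0.80 on the last two noise features of each time
    point (deliberately above the 70% removal threshold); planted
    markers and clinical scores stay at 0.05 / 0.
    """

    n_patients: int = 61
    prevalence: float = 0.35
    timepoints: tuple[str, ...] = STUDY_TIMEPOINTS
    n_features_per_timepoint: tuple[int, ...] = STUDY_FEATURES_PER_TP
    planted_markers: tuple[tuple[str, float], ...] = STUDY_MARKERS
    clinical_scores: tuple[tuple[str, float], ...] = STUDY_CLINICAL
    block_correlation: float = 0.5
    block_size: int = 5
    missing_rates: dict[str, float] | None = None
    missing_outcome_dependence: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie strictly in (0,1), got {self.prevalence}")
        if len(self.timepoints) != len(self.n_features_per_timepoint):
            raise ValueError("n_features_per_timepoint must match timepoints in length")
        if any(n < 1 for n in self.n_features_per_timepoint):
            raise ValueError("n_features_per_timepoint entries must be positive")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError(f"block_correlation must lie in [0,1), got {self.block_correlation}")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        n_clin = len(self.clinical_scores)
        counts: dict[str, int] = {tp: 0 for tp in self.timepoints}
        for tp, _ in self.planted_markers:
            if tp not in counts:
                raise ValueError(f"planted_markers references unknown timepoint {tp!r}")
            counts[tp] += 1
        for tp, n_feat, n_pl in zip(self.timepoints, self.n_features_per_timepoint, counts.values()):
            if n_pl + n_clin > n_feat:
                raise ValueError(
                    f"planted_markers + clinical_scores exceed feature count at {tp!r}"
                )
        if self.missing_rates is not None:
            for name, rate in self.missing_rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"missing_rates[{name!r}] must lie in [0,1], got {rate}")

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["n_features_per_timepoint"] = list(self.n_features_per_timepoint)
        d["planted_markers"] = [list(m) for m in self.planted_markers]
        d["clinical_scores"] = [list(c) for c in self.clinical_scores]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for key in ("timepoints", "n_features_per_timepoint"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("planted_markers", "clinical_scores"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        return cls(**d)


def study_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The study-shaped default cohort spec (61 x 68/68/67)."""
    return dataclasses.replace(SyntheticSpec(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Which generated features carry signal, and how much.

    ``informative`` maps feature name to planted effect size ``d``
    (clinical scores included); ``noise`` lists every other feature.
    Together they partition the generated features.
    """

    informative: dict[str, float] = field(default_factory=dict)
    noise: list[str] = field(default_factory=list)

    @property
    def markers(self) -> list[str]:
        """Informative non-clinical features (the planted immune markers)."""
        return [f for f in self.informative if "_" in f and not f.split("_")[0].isupper()]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"informative": self.informative, "noise": self.noise}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(informative=d["informative"], noise=list(d["noise"]))


def _feature_names(spec: SyntheticSpec) -> tuple[dict[str, list[str]], list[str]]:
    """Per-timepoint immune feature names (planted first) and clinical names."""
    clinical = [name for name, _ in spec.clinical_scores]
    per_tp: dict[str, list[str]] = {}
    for tp, n_feat in zip(spec.timepoints, spec.n_features_per_timepoint):
        n_planted = sum(1 for t, _ in spec.planted_markers if t == tp)
        n_noise = n_feat - len(clinical) - n_planted
        names = [f"marker{i+1}_{tp}" for i in range(n_planted)]
        names += [f"n{i+1:03d}_{tp}" for i in range(n_noise)]
        per_tp[tp] = names
    return per_tp, clinical


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort (no missingness yet) and its ground truth.

    Outcome labels are iid Bernoulli(prevalence).  Planted markers and
    clinical scores are group-conditional Gaussians shifted by their
    effect size; noise features share a latent factor per block of
    ``block_size`` giving within-block correlation ``block_correlation``;
    all marginal variances are 1.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    s_outcome, s_clinical, s_features = ss.spawn(3)
    n = spec.n_patients
    rng = np.random.default_rng(s_outcome)
    y = (rng.random(n) < spec.prevalence).astype(int)
    shift = y.astype(float)  # 1 in the event group

    per_tp, clinical_names = _feature_names(spec)
    truth = GroundTruth()
    cols: dict[str, np.ndarray] = {}

    rng_f = np.random.default_rng(s_features)
    rho = spec.block_correlation
    for tp in spec.timepoints:
        names = per_tp[tp]
        ds = [d for t, d in spec.planted_markers if t == tp]
        n_planted = len(ds)
        for name, d in zip(names[:n_planted], ds):
            cols[name] = rng_f.standard_normal(n) + d * shift
            truth.informative[name] = d
        noise_names = names[n_planted:]
        j = 0
        while j < len(noise_names):
            block = noise_names[j : j + spec.block_size]
            latent = rng_f.standard_normal(n)
            for name in block:
                eps = rng_f.standard_normal(n)
                cols[name] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
                truth.noise.append(name)
            j += spec.block_size

    rng_c = np.random.default_rng(s_clinical)
    for name, d in spec.clinical_scores:
        cols[name] = rng_c.standard_normal(n) + d * shift
        truth.informative[name] = d

    order: list[str] = []
    meta_tp: list[str] = []
    meta_role: list[str] = []
    for tp in spec.timepoints:
        order += per_tp[tp]
        meta_tp += [tp] * len(per_tp[tp])
        meta_role += ["immune"] * len(per_tp[tp])
    order += clinical_names
    meta_tp += [ALL_TIMEPOINTS] * len(clinical_names)
    meta_role += ["clinical"] * len(clinical_names)

    patients = [f"P{i+1:03d}" for i in range(n)]
    data = pd.DataFrame({name: cols[name] for name in order}, index=patients)
    outcome = pd.Series(y, index=patients, name="MODS")
    feature_meta = pd.DataFrame({"timepoint": meta_tp, "role": meta_role}, index=order)
    return CohortTable(data, outcome, feature_meta), truth


def _default_missing_rates(cohort: CohortTable, spec: SyntheticSpec) -> dict[str, float]:
    rates: dict[str, float] = {}
    for tp in spec.timepoints:
        immune = [
            f
            for f in cohort.feature_meta.index[
                (cohort.feature_meta["timepoint"] == tp)
                & (cohort.feature_meta["role"] == "immune")
            ]
        ]
        for f in immune:
            rates[f] = 0.05
        heavy = [f for f in immune if f not in dict(spec.planted_markers)][-2:]
        for f in heavy:
            rates[f] = 0.80
    return rates


def inject_missingness(cohort: CohortTable, spec: SyntheticSpec) -> CohortTable:
    """Mask entries of each feature independently at its per-feature rate.

    Masking is MCAR unless ``spec.missing_outcome_dependence`` is nonzero,
    in which case the masking probability for event-group patients is
    shifted on the log-odds scale by that amount (a deliberately simple
    MNAR switch, off by default).  Reproducible from ``spec.seed``.
    """
    spec.validate()
    if spec.missing_rates is None:
        rates = _default_missing_rates(cohort, spec)
    else:
        rates = spec.missing_rates
    unknown = set(rates) - set(cohort.data.columns)
    if unknown:
        raise ValueError(f"missing_rates names unknown features: {sorted(unknown)}")
    ss = np.random.SeedSequence(spec.seed)
    (_, _, _, s_missing) = ss.spawn(4)
    rng = np.random.default_rng(s_missing)
    out = cohort.copy()
    y = out.outcome.to_numpy()
    delta = spec.missing_outcome_dependence
    for name in out.data.columns:
        rate = rates.get(name, 0.0)
        if rate <= 0.0:
            continue
        p = np.full(len(y), rate)
        if delta != 0.0 and 0.0 < rate < 1.0:
            logit = np.log(rate / (1.0 - rate)) + delta * y
            p = 1.0 / (1.0 + np.exp(-logit))
        mask = rng.random(len(y)) < p
        col = out.data[name].to_numpy(dtype=float, copy=True)
        col[mask] = np.nan
        out.data[name] = col
    return out
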