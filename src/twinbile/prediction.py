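"""Random-forest prediction of metabolites from microbiome profiles.

Each metabolite is predicted from species relative abundances with a
random-forest regressor (performance: per-fold Spearman correlation of
observed vs predicted) and, after dichotomizing the response into its
top and bottom quartiles, a random-forest classifier (performance:
per-fold AUC). Cross-validation is twin-aware: whenever an individual is
in a test fold, every co-family member is removed from that fold's
training set, so family-shared variance cannot leak into the apparent
predictive signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "MicrobiomeProfile",
    "FoldAssignment",
    "PredictionPerformance",
    "filter_near_zero_variance",
    "make_twin_aware_folds",
    "run_rf_regressor",
    "dichotomize_quartiles",
    "run_rf_classifier",
    "mann_whitney_auc",
    "summarize_performance",
    "predict_metabolite",
]


@dataclass
class MicrobiomeProfile:
    """Samples x species relative-abundance matrix (rows sum to 1)."""

    abundances: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.abundances.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("relative abundances must be nonnegative")
        sums = vals.sum(axis=1)
        if vals.shape[1] and not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"row {bad} sums to {sums[bad]:.6g}, expected 1")

    @property
    def species_names(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.abundances.index)


@dataclass
class FoldAssignment:
    """k-fold split with per-fold family-purged training sets."""

    fold_id: np.ndarray  # fold index (0..k-1) per sample
    excluded: list[np.ndarray]  # per fold: training samples purged for kinship
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        out = np.flatnonzero(self.fold_id != fold)
        return np.setdiff1d(out, self.excluded[fold], assume_unique=False)


@dataclass
class PredictionPerformance:
    metabolite: str
    per_fold_rho: np.ndarray
    per_fold_auc: np.ndarray
    mean_rho: float
    mean_auc: float
    ci_rho: tuple[float, float] | None
    ci_auc: tuple[float, float] | None


def filter_near_zero_variance(
    profile: MicrobiomeProfile, freq_ratio: float = 19.0, unique_frac: float = 0.10
) -> tuple[MicrobiomeProfile, list[str]]:
    """Drop species with zero or near-zero variance.

    A species is near-zero-variance when the ratio of the most common to
    the second most common value exceeds ``freq_ratio`` AND the fraction
    of distinct values is below ``unique_frac`` (the conventional
    screening rule). Returns the filtered profile, renormalized to unit
    row sums, and the dropped names.
    """
    df = profile.abundances
    if df.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dropped = []
    for name in df.columns:
        col = df[name].to_numpy()
        counts = pd.Series(col).value_counts().to_numpy()
        if len(counts) == 1:
            dropped.append(name)
            continue
        ratio = counts[0] / counts[1]
        if ratio > freq_ratio and len(counts) / len(col) < unique_frac:
            dropped.append(name)
    kept = df.drop(columns=dropped)
    vals = kept.to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    out = pd.DataFrame(vals / sums, index=kept.index, columns=kept.columns)
    return MicrobiomeProfile(out), dropped


def make_twin_aware_folds(
    meta: pd.DataFrame, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Randomly split samples into k folds, then purge co-family members.

    Randomization is at the individual level: samples are permuted and
    dealt into k near-equal folds. For each fold, any training sample
    sharing a ``family_id`` with a test sample is excluded from that
    fold's training set.
    """
    n = len(meta)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_id[chunk] = f
    fam = meta["family_id"].to_numpy()
    excluded = []
    for f in range(k):
        test_fams = set(fam[fold_id == f])
        mask = (fold_id != f) & np.isin(fam, list(test_fams))
        excluded.append(np.flatnonzero(mask))
    return FoldAssignment(fold_id=fold_id, excluded=excluded, k=k)


def make_naive_folds(meta: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Plain k-fold split with no family purge (for leakage comparisons)."""
    fa = make_twin_aware_folds(meta, k=k, seed=seed)
    return FoldAssignment(fold_id=fa.fold_id, excluded=[np.array([], int)] * k, k=k)


def _mtry_regressor(p: int) -> int:
    return max(1, p // 3)


def _mtry_classifier(p: int) -> int:
    return max(1, int(np.sqrt(p)))


def run_rf_regressor(
    profile: MicrobiomeProfile,
    target: np.ndarray,
    folds: FoldAssignment,
    ntree: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-fold Spearman rho of observed vs out-of-fold RF predictions.

    mtry defaults to floor(p/3), floored at 1. A fold whose training
    target is constant yields NaN for that fold with a warning.
    """
    X = profile.abundances.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("target length does not match profile samples")
    mtry = mtry or _mtry_regressor(X.shape[1])
    rhos = np.full(folds.k, np.nan)
    for f in range(folds.k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        if np.ptp(y[tr]) == 0:
            warnings.warn(f"constant training target in fold {f}", stacklevel=2)
            continue
        rf = RandomForestRegressor(
            n_estimators=ntree,
            max_features=mtry,
            random_state=seed + f,
            n_jobs=1,
        ).fit(X[tr], y[tr])
        pred = rf.predict(X[te])
        rhos[f] = stats.spearmanr(y[te], pred).statistic
    return rhos


def dichotomize_quartiles(target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label bottom-quartile samples 0 and top-quartile samples 1.

    Samples at or below the 25th percentile form class 0, at or above the
    75th percentile class 1; the middle half is excluded. Ties straddling
    the 25th percentile all go to class 0 (and symmetrically at the 75th).
    Returns (labels over kept samples, boolean keep mask).
    """
    y = np.asarray(target, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 samples to dichotomize quartiles")
    if np.ptp(y) == 0:
        raise ValueError("constant response: quartile classes undefined")
    q25, q75 = np.percentile(y, [25, 75])
    low = y <= q25
    high = y >= q75
    keep = low | high
    labels = np.where(high[keep], 1, 0)
    return labels, keep


def mann_whitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation; midranks credit ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def run_rf_classifier(
    profile: MicrobiomeProfile,
    labels: np.ndarray,
    folds: FoldAssignment,
    ntree: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-fold AUC of out-of-fold predicted class-1 probabilities.

    mtry defaults to floor(sqrt(p)), floored at 1. A test fold containing
    a single class yields NaN for that fold with a warning.
    """
    X = profile.abundances.to_numpy(dtype=float)
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match profile samples")
    mtry = mtry or _mtry_classifier(X.shape[1])
    aucs = np.full(folds.k, np.nan)
    for f in range(folds.k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        if len(np.unique(y[te])) < 2:
            warnings.warn(f"single-class test set in fold {f}", stacklevel=2)
            continue
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"single-class training set in fold {f}", stacklevel=2)
            continue
        rf = RandomForestClassifier(
            n_estimators=ntree,
            max_features=mtry,
            random_state=seed + f,
            n_jobs=1,
        ).fit(X[tr], y[tr])
        prob1 = rf.predict_proba(X[te])[:, list(rf.classes_).index(1)]
        aucs[f] = mann_whitney_auc(y[te], prob1)
    return aucs


def summarize_performance(
    per_fold: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float] | None]:
    """Cross-fold mean and t-based CI over the defined (non-NaN) folds."""
    vals = np.asarray(per_fold, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined fold values")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    sem = vals.std(ddof=1) / np.sqrt(vals.size)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=vals.size - 1)
    return mean, (mean - tcrit * sem, mean + tcrit * sem)


def predict_metabolite(
    profile: MicrobiomeProfile,
    meta: pd.DataFrame,
    target: np.ndarray,
    name: str = "metabolite",
    k: int = 5,
    ntree: int = 1000,
    seed: int = 0,
    twin_aware: bool = True,
) -> PredictionPerformance:
    """Regression + quartile-classification performance for one metabolite.

    The regressor uses all samples. The classifier drops the middle two
    quartiles first and rebuilds folds on the kept subset (with a derived
    seed) so fold sizes stay balanced.
    """
    maker = make_twin_aware_folds if twin_aware else make_naive_folds
    folds = maker(meta, k=k, seed=seed)
    rhos = run_rf_regressor(profile, target, folds, ntree=ntree, seed=seed)

    labels, keep = dichotomize_quartiles(np.asarray(target, dtype=float))
    sub_profile = MicrobiomeProfile(profile.abundances.loc[keep])
    sub_meta = meta.loc[keep].reset_index(drop=True)
    sub_folds = maker(sub_meta, k=k, seed=seed + 1)
    aucs = run_rf_classifier(sub_profile, labels, sub_folds, ntree=ntree, seed=seed)

    mean_rho, ci_rho = summarize_performance(rhos)
    mean_auc, ci_auc = summarize_performance(aucs)
    return PredictionPerformance(
        metabolite=name,
        per_fold_rho=rhos,
        per_fold_auc=aucs,
        mean_rho=mean_rho,
        mean_auc=mean_auc,
        ci_rho=ci_rho,
        ci_auc=ci_auc,
    )
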