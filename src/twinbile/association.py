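"""Association statistics for metabolite-phenotype and species screens.

Covers the cross-sectional statistics used around the prediction models:
covariate-adjusted partial Spearman correlations with Benjamini-Hochberg
FDR, prevalence filtering, two-cohort directional concordance,
post-prandial peak/delta summaries and linear models on them,
DerSimonian-Laird random-effects inverse-variance meta-analysis, paired
t-tests for before/after interventions, and complete-linkage clustering
of species association profiles for heatmap ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .prediction import MicrobiomeProfile

__all__ = [
    "AssociationRecord",
    "MealSummary",
    "MetaResult",
    "prevalence_filter",
    "partial_spearman",
    "species_screen",
    "bh_fdr",
    "replicate_concordance",
    "summarize_meal",
    "linear_association",
    "meta_random_effects",
    "paired_ttest",
    "cluster_species",
]


@dataclass
class AssociationRecord:
    feature: str
    outcome: str
    estimate: float
    se: float | None
    ci: tuple[float, float] | None
    p: float
    q: float | None
    n: int
    cohort: str = ""
    extra: dict | None = None


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    ci: tuple[float, float]
    p: float
    tau2: float
    betas: np.ndarray
    ses: np.ndarray


def prevalence_filter(
    profile: MicrobiomeProfile, threshold: float = 0.20
) -> list[str]:
    """Species with nonzero abundance in strictly more than ``threshold``
    of samples."""
    prev = (profile.abundances > 0).mean(axis=0)
    return list(prev.index[prev > threshold])


def _rank_residuals(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Average-rank transform, then residualize on intercept + covariates."""
    ranks = stats.rankdata(values, method="average", axis=0).astype(float)
    if ranks.ndim == 1:
        ranks = ranks[:, None]
    n = ranks.shape[0]
    design = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        design = np.column_stack([design, covariates])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ coef


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Partial Spearman correlation of x and y given covariates.

    Both variables are rank-transformed (average ranks), residualized on
    an intercept plus the covariates by least squares, and the Pearson
    correlation of the residuals is returned. The p-value uses the t
    transform with n - 2 - n_covariates degrees of freedom. With no
    covariates this reduces to the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None
    n_cov = 0
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        n_cov = cov.shape[1]
    n = len(x)
    if n <= n_cov + 2:
        raise ValueError("too few samples for the covariate count")
    rx = _rank_residuals(x, cov)[:, 0]
    ry = _rank_residuals(y, cov)[:, 0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero residual variance")
    rho = float(np.dot(rx, ry) / (n * sx * sy))
    df = n - 2 - n_cov
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) >= 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt(df / (1.0 - rho_c * rho_c))
        p = float(2.0 * stats.t.sf(abs(t), df=df))
    return rho, p, n


def species_screen(
    profile: MicrobiomeProfile,
    trait: np.ndarray,
    covariates: pd.DataFrame | None = None,
    prevalence: float = 0.20,
    outcome: str = "trait",
    cohort: str = "",
) -> pd.DataFrame:
    """Prevalence-filtered partial-Spearman screen with per-screen BH FDR.

    A covariate that is constant (e.g. sex in an all-female cohort) is
    dropped automatically. The screen is vectorized across species; q
    values come from Benjamini-Hochberg applied to this screen alone.
    """
    keep = prevalence_filter(profile, prevalence)
    X = profile.abundances[keep].to_numpy(dtype=float)
    y = np.asarray(trait, dtype=float)
    cov = None
    if covariates is not None:
        nonconst = covariates.loc[:, covariates.nunique() > 1]
        cov = nonconst.to_numpy(dtype=float) if nonconst.shape[1] else None
    n, n_cov = len(y), 0 if cov is None else cov.shape[1]
    rx = _rank_residuals(X, cov)
    ry = _rank_residuals(y, cov)[:, 0]
    sx = rx.std(axis=0)
    sy = ry.std()
    if sy == 0 or (sx == 0).any():
        raise ValueError("zero residual variance in screen")
    rho = (rx.T @ ry) / (n * sx * sy)
    df = n - 2 - n_cov
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    tvals = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df)
    qvals = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "feature": keep,
            "outcome": outcome,
            "estimate": rho,
            "p": pvals,
            "q": qvals,
            "n": n,
            "cohort": cohort,
        }
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def replicate_concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    q_disc: float = 0.05,
    p_val: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Features significant and direction-concordant across two cohorts.

    Keeps features with BH q < ``q_disc`` in the discovery screen, nominal
    p < ``p_val`` in the validation screen, and the same estimate sign in
    both. Features absent from the validation screen are reported
    separately rather than silently dropped.
    """
    val = validation.set_index("feature")
    concordant, missing = [], []
    for _, row in discovery.iterrows():
        if row["q"] >= q_disc:
            continue
        if row["feature"] not in val.index:
            missing.append(row["feature"])
            continue
        v = val.loc[row["feature"]]
        if v["p"] < p_val and np.sign(v["estimate"]) == np.sign(row["estimate"]):
            concordant.append(row["feature"])
    return concordant, missing


@dataclass
class MealSummary:
    sample_id: object
    analyte: str
    baseline: float
    peak: float
    delta: float
    window_hours: float


def summarize_meal(
    timeseries: pd.DataFrame, analyte: str, window_hours: float
) -> pd.DataFrame:
    """Baseline / post-prandial peak / delta per sample.

    ``timeseries`` is long format with columns sample_id, analyte,
    timepoint_min, value. Baseline is the value at time 0; the peak is the
    maximum over 0 < t <= window (the fasting sample is not a candidate
    post-prandial peak), so delta = peak - baseline may be negative for a
    falling trajectory. A sample without a time-0 record is an error.
    """
    sub = timeseries[timeseries["analyte"] == analyte]
    rows = []
    for sid, grp in sub.groupby("sample_id", sort=True):
        base = grp.loc[grp["timepoint_min"] == 0, "value"]
        if base.empty:
            raise ValueError(f"sample {sid!r} lacks a time-0 record for {analyte!r}")
        window = grp[
            (grp["timepoint_min"] > 0) & (grp["timepoint_min"] <= window_hours * 60)
        ]
        if window.empty:
            raise ValueError(f"sample {sid!r} has no in-window record for {analyte!r}")
        baseline = float(base.iloc[0])
        peak = float(window["value"].max())
        rows.append(
            {
                "sample_id": sid,
                "analyte": analyte,
                "baseline": baseline,
                "peak": peak,
                "delta": peak - baseline,
                "window_hours": window_hours,
            }
        )
    return pd.DataFrame(rows)


def linear_association(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
    exposure_name: str = "exposure",
    cohort: str = "",
) -> AssociationRecord:
    """OLS of outcome on intercept + exposure + covariates.

    Returns the exposure coefficient with its t-based 95% CI and p-value;
    the model R-squared and F statistic ride along in ``extra`` (used for
    the no-covariate appetite correlation). A rank-deficient design is an
    error naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    cols = [exposure_name]
    design = x[:, None]
    if covariates is not None and covariates.shape[1]:
        design = np.column_stack([design, covariates.to_numpy(dtype=float)])
        cols += list(covariates.columns)
    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if design.shape[1] < 2:
            raise ValueError(f"rank-deficient design: column {cols[0]!r} is constant")
        corr = np.atleast_2d(np.corrcoef(design, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(f"rank-deficient design: columns {cols[i]!r} and {cols[j]!r}")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few samples for the design")
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi = fit.conf_int()[1]
    return AssociationRecord(
        feature=exposure_name,
        outcome=outcome_name,
        estimate=beta,
        se=se,
        ci=(float(lo), float(hi)),
        p=float(fit.pvalues[1]),
        q=None,
        n=len(y),
        cohort=cohort,
        extra={
            "r_squared": float(fit.rsquared),
            "f_stat": float(fit.fvalue),
            "df_model": int(fit.df_model),
            "df_resid": int(fit.df_resid),
        },
    )


def tertile_code(values: np.ndarray) -> np.ndarray:
    """Code a vector 0/1/2 by sample tertiles (midrank ties at boundaries)."""
    v = np.asarray(values, dtype=float)
    t1, t2 = np.quantile(v, [1 / 3, 2 / 3])
    return np.where(v <= t1, 0, np.where(v <= t2, 1, 2))


def meta_random_effects(betas: np.ndarray, ses: np.ndarray) -> MetaResult:
    """DerSimonian-Laird random-effects inverse-variance pooling.

    With fixed-effect weights w_i = 1/se_i^2, heterogeneity
    Q = sum w_i (b_i - b_fixed)^2 and
    tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i)).
    The pooled estimate reweights by w*_i = 1/(se_i^2 + tau^2); CI and
    p-value are Wald. With tau^2 = 0 this reduces exactly to fixed-effect
    inverse-variance pooling.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    b_fixed = np.sum(w * b) / np.sum(w)
    q_stat = float(np.sum(w * (b - b_fixed) ** 2))
    k = b.size
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q_stat - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    zc = stats.norm.ppf(0.975)
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        ci=(pooled - zc * pooled_se, pooled + zc * pooled_se),
        p=p,
        tau2=float(tau2),
        betas=b,
        ses=s,
    )


def paired_ttest(
    before: np.ndarray, after: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Mean of (after - before) with t-based 95% CI and two-sided p.

    Zero difference variance (e.g. a constant shift) leaves the t
    statistic undefined and is an error.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if len(a) != len(b):
        raise ValueError("before/after must be paired")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        raise ValueError("zero difference variance: paired t undefined")
    mean = float(diff.mean())
    sem = diff.std(ddof=1) / np.sqrt(len(diff))
    tcrit = stats.t.ppf(0.975, df=len(diff) - 1)
    p = float(stats.ttest_rel(a, b).pvalue)
    return mean, (mean - tcrit * sem, mean + tcrit * sem), p


def cluster_species(assoc_matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Complete-linkage clustering of species association profiles.

    Rows are species, columns association estimates (e.g. per
    biofluid x cohort). Distances are Euclidean; linkage is complete
    (cluster distance = max pairwise distance). Returns the deterministic
    leaf order (ties broken by the linkage algorithm's stable ordering of
    original row indices) and the linkage matrix.
    """
    if assoc_matrix.isna().any().any():
        raise ValueError("association matrix has missing entries")
    if assoc_matrix.shape[0] < 2:
        return list(assoc_matrix.index), np.empty((0, 4))
    Z = hierarchy.linkage(
        assoc_matrix.to_numpy(dtype=float), method="complete", metric="euclidean"
    )
    order = hierarchy.leaves_list(Z)
    return [assoc_matrix.index[i] for i in order], Z
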