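"""Classical twin variance decomposition by maximum likelihood.

A trait measured on monozygotic (MZ) and dizygotic (DZ) twin pairs plus
unpaired singletons is decomposed into additive-genetic (A), common-
environment (C) and unique-environment (E) variance. Under the standard
additive model MZ co-twins share all of A and all of C, DZ co-twins share
half of A and all of C, so the expected within-pair correlations are

    r_MZ = a2 + c2        r_DZ = 0.5 * a2 + c2

where a2, c2, e2 are the variance shares (a2 is the narrow-sense
heritability h^2). Each pair contributes a bivariate-normal likelihood
term with common mean and total variance across zygosity groups;
singletons contribute univariate terms and therefore inform the mean and
total variance only. The saturated model frees mean, variance and
covariance per zygosity group and serves as the fit ceiling for AIC
comparison against the ACE, AE, CE and E submodels.

Confidence intervals on the variance shares are profile-likelihood
intervals (chi-square 1-df cutoff), truncated to [0, 1]; a share
estimated on the boundary yields a one-sided interval with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinCohort",
    "VarianceComponents",
    "twin_loglik",
    "fit_twin_model",
    "fit_all_models",
    "select_model",
    "confidence_intervals",
    "heritability_table",
]

MODELS = ("saturated", "ACE", "AE", "CE", "E")
# preference order for AIC ties (after fewest-parameters)
_TIE_ORDER = {"ACE": 0, "AE": 1, "CE": 2, "E": 3, "saturated": 4}

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class TwinCohort:
    """Individuals with family structure, zygosity, covariates and traits.

    ``data`` must contain ``sample_id``, ``family_id`` and ``zygosity``
    (MZ / DZ / SINGLETON) columns; every family_id maps to one or two
    individuals and a two-person family has a single zygosity.
    """

    data: pd.DataFrame
    truth: dict | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "family_id", "zygosity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        sizes = self.data.groupby("family_id").size()
        if (sizes > 2).any():
            bad = sizes.index[sizes > 2][0]
            raise ValueError(f"family {bad!r} has more than 2 members")
        zyg = set(self.data["zygosity"].unique()) - {"MZ", "DZ", "SINGLETON"}
        if zyg:
            raise ValueError(f"unknown zygosity labels {sorted(zyg)}")

    def pairs_and_singles(
        self, trait: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (mz_pairs, dz_pairs, singles) trait arrays.

        Pair arrays have shape (n_pairs, 2) in family order; member order
        within a pair is as stored (the likelihood is exchangeable).
        """
        if trait not in self.data.columns:
            raise KeyError(f"trait {trait!r} not in cohort table")
        vals = self.data[trait].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"trait {trait!r} has missing values; preprocess first")
        mz, dz, single = [], [], []
        for _, grp in self.data.groupby("family_id", sort=True):
            v = grp[trait].to_numpy(dtype=float)
            if len(grp) == 1:
                single.append(v[0])
                continue
            z = grp["zygosity"].iloc[0]
            if grp["zygosity"].nunique() != 1:
                raise ValueError(
                    f"family {grp['family_id'].iloc[0]!r} mixes zygosities"
                )
            (mz if z == "MZ" else dz).append(v)
        to2 = lambda x: np.asarray(x, dtype=float).reshape(-1, 2)
        return to2(mz), to2(dz), np.asarray(single, dtype=float)


@dataclass
class VarianceComponents:
    """One fitted twin model for one trait."""

    model: str
    a2: float
    c2: float
    e2: float
    total_variance: float
    loglik: float
    n_params: int
    ci_a2: tuple[float, float] | None = None
    ci_c2: tuple[float, float] | None = None
    ci_e2: tuple[float, float] | None = None
    boundary: dict = field(default_factory=dict)
    trait: str | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def _pair_ll(pairs: np.ndarray, mu: float, var: float, r: float) -> float:
    """Sum of exchangeable bivariate-normal log densities over pairs."""
    if pairs.size == 0:
        return 0.0
    q = 1.0 - r * r
    z1 = pairs[:, 0] - mu
    z2 = pairs[:, 1] - mu
    quad = (z1 * z1 + z2 * z2 - 2.0 * r * z1 * z2) / (var * q)
    return float(np.sum(-_LOG2PI - math.log(var) - 0.5 * math.log(q) - 0.5 * quad))


def _single_ll(vals: np.ndarray, mu: float, var: float) -> float:
    if vals.size == 0:
        return 0.0
    z = vals - mu
    return float(np.sum(-0.5 * (_LOG2PI + math.log(var) + z * z / var)))


def twin_loglik(
    mz: np.ndarray,
    dz: np.ndarray,
    singles: np.ndarray,
    mu: float,
    total_variance: float,
    a2: float,
    c2: float,
) -> float:
    """Log-likelihood of an ACE-family model at fixed parameter values.

    ``a2`` and ``c2`` are variance *shares*; the implied within-pair
    correlations are a2 + c2 (MZ) and 0.5 a2 + c2 (DZ). Exposed so the
    likelihood can be checked against an external bivariate-normal
    density at pinned parameters.
    """
    if total_variance <= 0:
        raise ValueError("total variance must be positive")
    r_mz = a2 + c2
    r_dz = 0.5 * a2 + c2
    return (
        _pair_ll(np.atleast_2d(mz) if np.size(mz) else np.empty((0, 2)), mu, total_variance, r_mz)
        + _pair_ll(np.atleast_2d(dz) if np.size(dz) else np.empty((0, 2)), mu, total_variance, r_dz)
        + _single_ll(np.asarray(singles, dtype=float), mu, total_variance)
    )


_SHARE_CAP = 1.0 - 1e-7  # keeps pair correlations away from the singular r=1


def _nll_factory(mz, dz, singles, model: str):
    """Negative log-likelihood over (mu, log var, free shares).

    Free-share layout: ACE -> (t1, t2) with a2 = t1, c2 = (1-t1) t2;
    AE -> (t1,) a2 = t1; CE -> (t1,) c2 = t1; E -> ().
    """

    def shares(theta):
        if model == "ACE":
            a2 = theta[2]
            c2 = (1.0 - theta[2]) * theta[3]
        elif model == "AE":
            a2, c2 = theta[2], 0.0
        elif model == "CE":
            a2, c2 = 0.0, theta[2]
        else:  # E
            a2, c2 = 0.0, 0.0
        return a2, c2

    def nll(theta):
        mu, logv = theta[0], theta[1]
        a2, c2 = shares(theta)
        return -twin_loglik(mz, dz, singles, mu, math.exp(logv), a2, c2)

    n_free = {"ACE": 2, "AE": 1, "CE": 1, "E": 0}[model]
    return nll, shares, n_free


def _moment_init(mz, dz, singles):
    allv = np.concatenate([mz.ravel(), dz.ravel(), singles])
    mu = float(np.mean(allv))
    var = float(np.var(allv)) or 1.0

    def _icc(p):
        if len(p) < 2:
            return 0.0
        z = (p - mu).ravel()
        cross = np.mean((p[:, 0] - mu) * (p[:, 1] - mu))
        return float(np.clip(cross / np.mean(z * z), -0.5, 0.99))

    r_mz, r_dz = _icc(mz), _icc(dz)
    a2 = np.clip(2.0 * (r_mz - r_dz), 0.0, 0.95)  # Falconer start
    c2 = np.clip(2.0 * r_dz - r_mz, 0.0, 0.95 - a2)
    return mu, var, float(a2), float(c2)


def fit_twin_model(
    cohort: TwinCohort,
    trait: str,
    model: str,
    n_restarts: int = 5,
    seed: int = 0,
) -> VarianceComponents:
    """Maximum-likelihood fit of one twin model to one trait.

    Non-saturated models share a grand mean and total variance across
    zygosity groups; the variance shares are constrained to [0, 1] (the
    optimizer works on the shares directly, so boundary estimates are
    allowed). The fit uses L-BFGS-B from a moment-based start plus random
    restarts; non-convergence of every start is an error carrying the
    optimizer status.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    mz, dz, singles = cohort.pairs_and_singles(trait)
    if model == "saturated":
        return _fit_saturated(mz, dz, singles, trait)
    if model in ("ACE", "AE") and (len(mz) < 2 or len(dz) < 2):
        raise ValueError("need at least 2 MZ and 2 DZ pairs to identify A")

    nll, shares, n_free = _nll_factory(mz, dz, singles, model)
    mu0, var0, a20, c20 = _moment_init(mz, dz, singles)
    if model == "ACE":
        t0 = [min(a20, _SHARE_CAP), min(c20 / max(1.0 - a20, 1e-6), _SHARE_CAP)]
    elif model == "AE":
        t0 = [min(a20 + c20, _SHARE_CAP)]
    elif model == "CE":
        t0 = [min(a20 / 2.0 + c20, _SHARE_CAP)]
    else:
        t0 = []
    bounds = [(None, None), (-50.0, 50.0)] + [(0.0, _SHARE_CAP)] * n_free

    rng = np.random.default_rng(seed)
    starts = [np.array([mu0, math.log(var0), *t0])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array(
                [
                    mu0 + rng.normal(0, 0.3) * math.sqrt(var0),
                    math.log(var0) + rng.normal(0, 0.3),
                    *rng.uniform(0.05, 0.9, size=n_free),
                ]
            )
        )

    best = None
    traces = []
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        traces.append(res)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"twin model {model} did not converge: {traces[-1].message}")

    mu, logv = best.x[0], best.x[1]
    a2, c2 = shares(best.x)
    return VarianceComponents(
        model=model,
        a2=float(a2),
        c2=float(c2),
        e2=float(1.0 - a2 - c2),
        total_variance=float(math.exp(logv)),
        loglik=float(-best.fun),
        n_params=2 + n_free,
        trait=trait,
    )


def _fit_saturated(mz, dz, singles, trait) -> VarianceComponents:
    """Closed-form ML fit of the exchangeable per-group saturated model."""
    ll = 0.0
    n_params = 0
    for pairs in (mz, dz):
        if len(pairs) == 0:
            continue
        mu = float(np.mean(pairs))
        var = float(np.mean((pairs - mu) ** 2))
        cov = float(np.mean((pairs[:, 0] - mu) * (pairs[:, 1] - mu)))
        r = np.clip(cov / var, -_SHARE_CAP, _SHARE_CAP)
        ll += _pair_ll(pairs, mu, var, float(r))
        n_params += 3
    if len(singles):
        mu = float(np.mean(singles))
        var = float(np.mean((singles - mu) ** 2))
        ll += _single_ll(singles, mu, var)
        n_params += 2
    return VarianceComponents(
        model="saturated",
        a2=float("nan"),
        c2=float("nan"),
        e2=float("nan"),
        total_variance=float("nan"),
        loglik=ll,
        n_params=n_params,
        trait=trait,
    )


def select_model(fits: list[VarianceComponents]) -> VarianceComponents:
    """Pick the fit with the lowest AIC.

    Ties (within 1e-9) go to the model with fewer parameters, then to the
    fixed order ACE, AE, CE, E, saturated.
    """
    if not fits:
        raise ValueError("no fits to select from")
    return min(
        fits,
        key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.n_params, _TIE_ORDER[f.model]),
    )


def _profile_nll(mz, dz, singles, model: str, component: str, value: float) -> float:
    """Minimized negative log-likelihood with one variance share pinned."""

    def make(theta_to_shares, n_free):
        def nll(theta):
            a2, c2 = theta_to_shares(theta)
            tot = a2 + c2
            if tot > _SHARE_CAP:  # keep pair correlation off the singular r=1
                a2, c2 = a2 * _SHARE_CAP / tot, c2 * _SHARE_CAP / tot
            return -twin_loglik(mz, dz, singles, theta[0], math.exp(theta[1]), a2, c2)

        return nll, n_free

    t = float(np.clip(value, 0.0, _SHARE_CAP))
    if model == "ACE":
        # one remaining share splits the leftover stick
        if component == "a2":
            nll, n_free = make(lambda th: (t, (1.0 - t) * th[2]), 1)
        elif component == "c2":
            nll, n_free = make(lambda th: ((1.0 - t) * th[2], t), 1)
        else:  # e2 pinned: a2 + c2 = 1 - t
            nll, n_free = make(
                lambda th: ((1.0 - t) * th[2], (1.0 - t) * (1.0 - th[2])), 1
            )
    elif model == "AE":
        s = t if component == "a2" else 1.0 - t
        nll, n_free = make(lambda th: (s, 0.0), 0)
    elif model == "CE":
        s = t if component == "c2" else 1.0 - t
        nll, n_free = make(lambda th: (0.0, s), 0)
    else:
        raise ValueError(f"no free shares to profile in model {model}")

    mu0, var0, _, _ = _moment_init(mz, dz, singles)
    x0 = np.array([mu0, math.log(var0)] + [0.5] * n_free)
    bounds = [(None, None), (-50.0, 50.0)] + [(0.0, 1.0)] * n_free
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    return float(res.fun)


def confidence_intervals(
    cohort: TwinCohort, fit: VarianceComponents, level: float = 0.95
) -> VarianceComponents:
    """Profile-likelihood intervals on the variance shares.

    For each share free in the model, the interval is the set of pinned
    values whose profile log-likelihood lies within chi2_{1,level}/2 of
    the maximum, truncated to [0, 1]. Shares fixed by the model get
    degenerate intervals; a point estimate on the boundary gives a
    one-sided interval recorded in ``fit.boundary``.
    """
    if fit.model == "saturated":
        raise ValueError("saturated model has no variance shares")
    mz, dz, singles = cohort.pairs_and_singles(fit.trait)
    crit = stats.chi2.ppf(level, df=1) / 2.0
    ll_max = fit.loglik
    point = {"a2": fit.a2, "c2": fit.c2, "e2": fit.e2}
    free = {"ACE": ("a2", "c2", "e2"), "AE": ("a2", "e2"), "CE": ("c2", "e2"), "E": ()}[
        fit.model
    ]
    cis: dict[str, tuple[float, float]] = {}
    boundary: dict[str, str] = {}
    for comp in ("a2", "c2", "e2"):
        p = point[comp]
        if comp not in free:
            cis[comp] = (p, p)
            continue

        def drop(t, comp=comp):
            return (_profile_nll(mz, dz, singles, fit.model, comp, t) + ll_max) - crit

        eps = 1e-6
        lo, hi = 0.0, 1.0
        if p > eps and drop(0.0) > 0:
            lo = optimize.brentq(drop, 0.0, p, xtol=1e-5)
        elif p <= eps:
            boundary[comp] = "lower"
        if p < 1.0 - eps and drop(1.0) > 0:
            hi = optimize.brentq(drop, p, 1.0, xtol=1e-5)
        elif p >= 1.0 - eps:
            boundary[comp] = "upper"
        cis[comp] = (float(lo), float(hi))
    return replace(
        fit, ci_a2=cis["a2"], ci_c2=cis["c2"], ci_e2=cis["e2"], boundary=boundary
    )


def fit_all_models(
    cohort: TwinCohort,
    trait: str,
    models: tuple[str, ...] = MODELS,
    seed: int = 0,
) -> list[VarianceComponents]:
    return [fit_twin_model(cohort, trait, m, seed=seed) for m in models]


def heritability_table(
    cohort: TwinCohort,
    traits: list[str],
    models: tuple[str, ...] = MODELS,
    ci: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit all models per trait, AIC-select, and tabulate the winners."""
    rows = []
    for trait in traits:
        fits = fit_all_models(cohort, trait, models, seed=seed)
        best = select_model(fits)
        if ci and best.model != "saturated":
            best = confidence_intervals(cohort, best)
        rows.append(
            {
                "trait": trait,
                "best_model": best.model,
                "a2": best.a2,
                "c2": best.c2,
                "e2": best.e2,
                "a2_lo": best.ci_a2[0] if best.ci_a2 else np.nan,
                "a2_hi": best.ci_a2[1] if best.ci_a2 else np.nan,
                **{f"aic_{f.model}": f.aic for f in fits},
            }
        )
    return pd.DataFrame(rows)
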