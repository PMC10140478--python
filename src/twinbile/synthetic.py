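"""Synthetic twin-cohort, microbiome and meal-response data with known truth.

Every generator is a pure function of its parameters and a seed, and
returns the planted ground truth alongside the data so each downstream
stage (preprocessing, heritability, prediction, association) can be
scored for parameter recovery.

The twin simulator draws, per trait, latent additive-genetic (shared
within MZ pairs, correlated 0.5 within DZ pairs), common-environment
(shared within any pair) and unique-environment factors, combined with
path coefficients sqrt(a2), sqrt(c2), sqrt(e2). The microbiome simulator
uses a zero-inflated log-normal: a latent Gaussian thresholded at the
target prevalence gates presence, a log-normal draws abundance, and rows
are closed to unit sum; an optional family factor correlates both
presence and abundance within families (needed to exercise family-level
leakage in cross-validation). Batch structure multiplies values by
per-batch scales and left-censors the lowest fraction of each metabolite
to missing, emulating detection limits. Meal responses place a
post-prandial bump on a flat baseline whose height is a linear function
of a chosen trait plus covariates plus noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import TwinCohort
from .prediction import MicrobiomeProfile
from .preprocessing import MetaboliteMatrix

__all__ = [
    "AceSpec",
    "CohortDesign",
    "CouplingSpec",
    "BatchSpec",
    "simulate_twin_cohort",
    "simulate_microbiome",
    "couple_metabolite",
    "apply_batch_structure",
    "simulate_postprandial",
]

DEFAULT_COVARIATES = (
    ("age", ("uniform", 35.0, 80.0)),
    ("bmi", ("normal", 26.0, 5.0)),
    ("sex", ("bernoulli", 0.5)),
)


@dataclass(frozen=True)
class AceSpec:
    """Variance shares and scale of one simulated trait."""

    a2: float
    c2: float
    e2: float
    trait_mean: float = 0.0
    trait_sd: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a2, self.c2, self.e2) < 0:
            raise ValueError("variance shares must be nonnegative")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ValueError("a2 + c2 + e2 must equal 1")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")


@dataclass(frozen=True)
class CohortDesign:
    """Twin-cohort layout: MZ/DZ pair counts, singletons, covariates."""

    n_mz_pairs: int
    n_dz_pairs: int
    n_singletons: int = 0
    covariate_specs: tuple = DEFAULT_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_singletons) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_individuals(self) -> int:
        return 2 * self.n_mz_pairs + 2 * self.n_dz_pairs + self.n_singletons


@dataclass(frozen=True)
class CouplingSpec:
    """Planted species -> metabolite effects."""

    causal_species: tuple
    effect_sizes: tuple
    noise_sd: float

    def __post_init__(self) -> None:
        if len(self.causal_species) != len(self.effect_sizes):
            raise ValueError("effect_sizes must match causal_species in length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class BatchSpec:
    """Instrument batches: multiplicative scales and left-censoring."""

    n_batches: int
    batch_scales: tuple
    censor_quantile: float = 0.0

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        if len(self.batch_scales) != self.n_batches:
            raise ValueError("batch_scales must match n_batches")
        if min(self.batch_scales) <= 0:
            raise ValueError("batch scales must be positive")
        if not (0.0 <= self.censor_quantile < 1.0):
            raise ValueError("censor_quantile must be in [0, 1)")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_covariate(rng: np.random.Generator, spec, size: int) -> np.ndarray:
    kind, *params = spec
    if kind == "uniform":
        return rng.uniform(params[0], params[1], size)
    if kind == "normal":
        return rng.normal(params[0], params[1], size)
    if kind == "bernoulli":
        return rng.binomial(1, params[0], size).astype(float)
    raise ValueError(f"unknown covariate distribution {kind!r}")


def simulate_twin_cohort(
    design: CohortDesign,
    traits: dict[str, AceSpec],
    covariate_betas: dict[str, dict[str, float]] | None = None,
) -> TwinCohort:
    """Simulate a twin cohort with ACE-structured traits.

    For each trait, an individual's value is
    ``mean + sd * (sqrt(a2) G + sqrt(c2) C + sqrt(e2) U)`` with G identical
    within MZ pairs and correlated 0.5 within DZ pairs, C identical within
    any pair, and U independent. Age is shared within a pair (twins are
    born together); sex is identical within MZ pairs. ``covariate_betas``
    optionally adds linear covariate effects per trait (so covariate
    adjustment can be exercised); the planted parameters are recorded in
    ``TwinCohort.truth``.
    """
    n_mz, n_dz, n_s = design.n_mz_pairs, design.n_dz_pairs, design.n_singletons
    n = design.n_individuals
    rngs = _spawn(design.seed, 2 + len(traits))

    fam_of_pair = [f"F{idx:05d}" for idx in range(n_mz + n_dz + n_s)]
    family_id, zygosity = [], []
    for i in range(n_mz):
        family_id += [fam_of_pair[i]] * 2
        zygosity += ["MZ"] * 2
    for i in range(n_dz):
        family_id += [fam_of_pair[n_mz + i]] * 2
        zygosity += ["DZ"] * 2
    for i in range(n_s):
        family_id.append(fam_of_pair[n_mz + n_dz + i])
        zygosity.append("SINGLETON")

    cov_rng = rngs[0]
    cov_cols: dict[str, np.ndarray] = {}
    n_pairs = n_mz + n_dz
    for name, spec in design.covariate_specs:
        if name == "age":  # shared within a pair
            per_fam = _draw_covariate(cov_rng, spec, n_pairs + n_s)
            vals = np.concatenate([np.repeat(per_fam[:n_pairs], 2), per_fam[n_pairs:]])
        elif name == "sex":  # identical within MZ pairs
            mz = np.repeat(_draw_covariate(cov_rng, spec, n_mz), 2)
            rest = _draw_covariate(cov_rng, spec, 2 * n_dz + n_s)
            vals = np.concatenate([mz, rest])
        else:
            vals = _draw_covariate(cov_rng, spec, n)
        cov_cols[name] = vals

    df = pd.DataFrame(
        {
            "sample_id": [f"S{idx:05d}" for idx in range(n)],
            "family_id": family_id,
            "zygosity": zygosity,
            **cov_cols,
            "cohort": "SIM",
        }
    )

    truth: dict = {"design": design, "traits": {}}
    for t_idx, (tname, spec) in enumerate(traits.items()):
        rng = rngs[2 + t_idx]
        a, c, e = math.sqrt(spec.a2), math.sqrt(spec.c2), math.sqrt(spec.e2)
        # genetic factor: shared for MZ, correlated 0.5 for DZ
        g_mz = np.repeat(rng.standard_normal(n_mz), 2)
        z1 = rng.standard_normal(n_dz)
        z2 = rng.standard_normal(n_dz)
        g_dz = np.empty(2 * n_dz)
        g_dz[0::2] = z1
        g_dz[1::2] = 0.5 * z1 + math.sqrt(0.75) * z2
        g_s = rng.standard_normal(n_s)
        g = np.concatenate([g_mz, g_dz, g_s])
        # common environment: shared within any pair
        cm = np.concatenate(
            [np.repeat(rng.standard_normal(n_pairs), 2), rng.standard_normal(n_s)]
        )
        u = rng.standard_normal(n)
        vals = spec.trait_mean + spec.trait_sd * (a * g + c * cm + e * u)
        betas = (covariate_betas or {}).get(tname, {})
        for cov_name, beta in betas.items():
            vals = vals + beta * cov_cols[cov_name]
        df[tname] = vals
        truth["traits"][tname] = {"spec": spec, "covariate_betas": betas}

    return TwinCohort(data=df, truth=truth)


def simulate_microbiome(
    n_samples: int,
    n_species: int,
    prevalence_profile: np.ndarray,
    seed: int = 0,
    family_ids: np.ndarray | None = None,
    family_rho: float = 0.0,
    log_sigma: float = 1.0,
    log_mu_sd: float = 1.5,
) -> MicrobiomeProfile:
    """Zero-inflated log-normal relative-abundance profiles.

    Presence of species j in a sample is gated by a latent standard
    Gaussian exceeding the ``1 - prevalence_j`` quantile, so realized
    prevalence matches ``prevalence_profile`` in expectation. Abundance
    where present is log-normal with a species-specific location (drawn
    once from N(0, log_mu_sd)) giving heavy right tails. With
    ``family_rho > 0`` and ``family_ids`` given, a family-level factor
    with variance share ``family_rho`` enters both the presence latent
    and the log-abundance, correlating co-family profiles while leaving
    marginal prevalence unchanged. Rows are closed to unit sum; a sample
    with no present species gets its highest-prevalence species.
    """
    if n_species == 0:
        raise ValueError("need at least one species")
    prev = np.asarray(prevalence_profile, dtype=float)
    if prev.shape != (n_species,):
        raise ValueError("prevalence_profile length must equal n_species")
    if ((prev < 0) | (prev > 1)).any():
        raise ValueError("prevalences must lie in [0, 1]")
    rng_mu, rng_fam, rng_ind, rng_ab = _spawn(seed, 4)

    mu = rng_mu.normal(0.0, log_mu_sd, n_species)
    if family_rho > 0 and family_ids is not None:
        fam = np.asarray(family_ids)
        codes = pd.factorize(fam)[0]
        fam_z = rng_fam.standard_normal((codes.max() + 1, n_species))[codes]
        lat = math.sqrt(family_rho) * fam_z + math.sqrt(1 - family_rho) * (
            rng_ind.standard_normal((n_samples, n_species))
        )
        ab_z = math.sqrt(family_rho) * fam_z + math.sqrt(1 - family_rho) * (
            rng_ab.standard_normal((n_samples, n_species))
        )
    else:
        lat = rng_ind.standard_normal((n_samples, n_species))
        ab_z = rng_ab.standard_normal((n_samples, n_species))

    present = lat > stats.norm.ppf(1.0 - prev)  # prev=1 -> threshold -inf
    raw = np.exp(mu + log_sigma * ab_z) * present
    empty = raw.sum(axis=1) == 0
    if empty.any():
        raw[empty, int(np.argmax(prev))] = np.exp(mu[int(np.argmax(prev))])
    rel = raw / raw.sum(axis=1, keepdims=True)
    return MicrobiomeProfile(
        pd.DataFrame(
            rel,
            index=[f"S{idx:05d}" for idx in range(n_samples)],
            columns=[f"sp_{j:04d}" for j in range(n_species)],
        )
    )


def couple_metabolite(
    profile: MicrobiomeProfile,
    coupling: CouplingSpec,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Plant a species -> metabolite signal.

    trait_i = sum_j effect_j * log1p(relative abundance of causal species
    j in sample i) + N(0, noise_sd). The report carries the realized
    signal variance and the implied ground-truth
    R^2 = var(signal) / (var(signal) + noise_sd^2).
    """
    ab = profile.abundances
    if ab.shape[0] == 0:
        raise ValueError("empty profile")
    p = ab.shape[1]
    idx = list(coupling.causal_species)
    if any(j >= p or j < 0 for j in idx):
        raise ValueError("causal species index out of range")
    rng = np.random.default_rng(seed)
    signal = np.zeros(ab.shape[0])
    for j, eff in zip(idx, coupling.effect_sizes):
        signal = signal + eff * np.log1p(ab.iloc[:, j].to_numpy())
    noise = rng.normal(0.0, coupling.noise_sd, ab.shape[0])
    var_sig = float(np.var(signal))
    denom = var_sig + coupling.noise_sd**2
    report = {
        "signal_var": var_sig,
        "noise_var": coupling.noise_sd**2,
        "r2": var_sig / denom if denom > 0 else 0.0,
        "causal_species": [ab.columns[j] for j in idx],
    }
    return signal + noise, report


def calibrated_coupling(
    profile: MicrobiomeProfile,
    causal_species: tuple,
    effect_sizes: tuple,
    target_r2: float = 0.5,
) -> CouplingSpec:
    """Choose noise_sd so the planted signal explains ``target_r2``."""
    signal = np.zeros(profile.abundances.shape[0])
    for j, eff in zip(causal_species, effect_sizes):
        signal = signal + eff * np.log1p(profile.abundances.iloc[:, j].to_numpy())
    var_sig = float(np.var(signal))
    noise_sd = math.sqrt(var_sig * (1.0 - target_r2) / target_r2)
    return CouplingSpec(tuple(causal_species), tuple(effect_sizes), noise_sd)


def apply_batch_structure(
    values: pd.DataFrame, spec: BatchSpec, seed: int = 0
) -> MetaboliteMatrix:
    """Impose instrument batches and detection-limit missingness.

    Samples are randomly assigned to batches, values multiplied by the
    batch scale, and per metabolite the lowest ``censor_quantile``
    fraction of the scaled values is set to missing (left-censoring; the
    minimum-imputation step downstream assumes exactly this mechanism).
    """
    if spec.n_batches > values.shape[0]:
        raise ValueError("more batches than samples")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    batch = rng.permuted(np.arange(n) % spec.n_batches)
    scales = np.asarray(spec.batch_scales, dtype=float)[batch]
    out = values.mul(scales, axis=0)
    if spec.censor_quantile > 0:
        k = int(math.floor(spec.censor_quantile * n))
        for col in out.columns:
            order = np.argsort(out[col].to_numpy(), kind="stable")
            out.iloc[order[:k], out.columns.get_loc(col)] = np.nan
    return MetaboliteMatrix(
        values=out,
        batch_labels=pd.Series([f"B{b}" for b in batch], index=values.index),
        stage="raw",
    )


def simulate_postprandial(
    trait: np.ndarray,
    beta: float,
    covariates: pd.DataFrame,
    timepoints: tuple = (0, 30, 120, 240, 360),
    seed: int = 0,
    analyte: str = "triglycerides",
    baseline_mean: float = 1.0,
    baseline_sd: float = 0.2,
    rise_intercept: float = 2.0,
    covariate_betas: dict[str, float] | None = None,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Meal-response trajectories whose peak is linear in the trait.

    Each sample gets a flat baseline plus a smooth post-prandial bump
    peaking mid-window; the bump height is
    ``rise_intercept + beta * trait + covariate effects + N(0, noise_sd)``
    so the trajectory peak equals baseline + that height and a regression
    of peak on trait (adjusting for the covariates) recovers ``beta``.
    Returns a long table (sample_id, analyte, timepoint_min, value) and
    the ground truth. Trajectory maxima never fall below the time-0 value
    because the bump is zero at the endpoints and the rise is reported
    as planted (a negative realized rise yields a flat trajectory).
    """
    trait = np.asarray(trait, dtype=float)
    if len(trait) != len(covariates):
        raise ValueError("trait length must match covariate rows")
    tps = tuple(timepoints)
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(seed)
    n = len(trait)
    betas = covariate_betas or {"age": 0.005, "bmi": 0.02}
    baseline = baseline_mean + rng.normal(0.0, baseline_sd, n)
    rise = rise_intercept + beta * trait + rng.normal(0.0, noise_sd, n)
    for name, b in betas.items():
        if name in covariates.columns:
            rise = rise + b * covariates[name].to_numpy(dtype=float)
    rise = np.maximum(rise, 0.0)  # trajectory never dips below baseline

    t = np.asarray(tps, dtype=float)
    t_max = t.max()
    bump = np.sin(np.pi * np.clip(t / t_max, 0, 1))  # 0 at both ends, max mid-window
    bump = bump / bump.max()  # peak over realized timepoints = baseline + rise exactly
    rows = []
    ids = (
        list(covariates.index)
        if not isinstance(covariates.index, pd.RangeIndex)
        else [f"S{idx:05d}" for idx in range(n)]
    )
    for i in range(n):
        for tp, bmp in zip(tps, bump):
            rows.append(
                {
                    "sample_id": ids[i],
                    "analyte": analyte,
                    "timepoint_min": int(tp),
                    "value": baseline[i] + rise[i] * bmp,
                }
            )
    truth = {
        "beta": beta,
        "covariate_betas": betas,
        "noise_sd": noise_sd,
        "rise_intercept": rise_intercept,
        "peak_timepoint_min": float(t[np.argmax(bump)]),
    }
    return pd.DataFrame(rows), truth
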