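"""End-to-end pipeline driver.

Runs (optionally) the synthetic-data generator, then the metabolite QC
chain, twin heritability with AIC model selection, twin-aware
random-forest prediction, and the species association screen, writing one
TSV per stage plus a YAML run report. Every output table carries the seed
and input checksums in comment headers, and a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import species_screen
from .heritability import TwinCohort, heritability_table
from .io import read_matrix, read_metadata, sha256_of, write_matrix, write_table
from .prediction import MicrobiomeProfile, filter_near_zero_variance, predict_metabolite
from .preprocessing import MetaboliteMatrix, run_preprocessing
from .synthetic import (
    AceSpec,
    BatchSpec,
    CohortDesign,
    apply_batch_structure,
    calibrated_coupling,
    couple_metabolite,
    simulate_microbiome,
    simulate_twin_cohort,
)

logger = logging.getLogger("twinbile")

__all__ = ["RunConfig", "run_pipeline", "simulate_dataset"]


@dataclass
class RunConfig:
    """Pipeline configuration with spec-level defaults."""

    seed: int = 0
    out_dir: str = "twinbile_out"
    # synthetic-data stage (skipped when input paths are given)
    simulate: bool = True
    n_mz_pairs: int = 120
    n_dz_pairs: int = 80
    n_singletons: int = 50
    n_species: int = 60
    trait_specs: dict = field(
        default_factory=lambda: {
            "ba_heritable": {"a2": 0.6, "c2": 0.1, "e2": 0.3},
            "ba_environmental": {"a2": 0.1, "c2": 0.1, "e2": 0.8},
        }
    )
    coupled_trait: str = "ba_microbial"
    coupled_r2: float = 0.5
    n_causal_species: int = 5
    n_batches: int = 3
    batch_scales: tuple = (1.0, 1.5, 0.7)
    censor_quantile: float = 0.10
    family_rho: float = 0.3
    # external inputs (used when simulate is false)
    metabolites_path: str | None = None
    metadata_path: str | None = None
    microbiome_path: str | None = None
    # thresholds / stage parameters
    max_missing: float = 0.20
    prevalence: float = 0.20
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    k_folds: int = 5
    ntree: int = 1000
    int_offset: str = "blom"
    # stage toggles
    run_heritability: bool = True
    run_predict: bool = True
    run_associate: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing", "prevalence", "q_threshold", "p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def simulate_dataset(cfg: RunConfig, out: Path) -> dict:
    """Generate and write the synthetic inputs; returns in-memory objects."""
    rng = np.random.default_rng(cfg.seed)
    design = CohortDesign(
        n_mz_pairs=cfg.n_mz_pairs,
        n_dz_pairs=cfg.n_dz_pairs,
        n_singletons=cfg.n_singletons,
        seed=cfg.seed,
    )
    traits = {
        name: AceSpec(**shares) for name, shares in cfg.trait_specs.items()
    }
    cohort = simulate_twin_cohort(design, traits)
    n = design.n_individuals

    prevalence = rng.uniform(0.1, 0.95, cfg.n_species)
    profile = simulate_microbiome(
        n,
        cfg.n_species,
        prevalence,
        seed=cfg.seed + 1,
        family_ids=cohort.data["family_id"].to_numpy(),
        family_rho=cfg.family_rho,
    )
    causal = tuple(rng.choice(cfg.n_species, cfg.n_causal_species, replace=False))
    effects = tuple(rng.choice([-1.0, 1.0], cfg.n_causal_species) * rng.uniform(0.5, 1.5, cfg.n_causal_species))
    coupling = calibrated_coupling(profile, causal, effects, target_r2=cfg.coupled_r2)
    coupled, coupling_report = couple_metabolite(profile, coupling, seed=cfg.seed + 2)

    # metabolite panel on a positive abundance scale (log-normal liabilities)
    liabilities = cohort.data[list(traits)].copy()
    liabilities[cfg.coupled_trait] = coupled
    raw = np.exp(liabilities)
    raw.index = cohort.data["sample_id"]
    matrix = apply_batch_structure(
        raw, BatchSpec(cfg.n_batches, tuple(cfg.batch_scales), cfg.censor_quantile),
        seed=cfg.seed + 3,
    )

    meta = cohort.data[["sample_id", "family_id", "zygosity", "age", "bmi", "sex", "cohort"]].copy()
    meta["batch"] = matrix.batch_labels.to_numpy()

    hdr = {"seed": cfg.seed, "twinbile_version": __version__}
    write_matrix(matrix.values, out / "metabolites_raw.tsv", hdr)
    write_matrix(profile.abundances, out / "microbiome.tsv", hdr)
    write_table(meta, out / "metadata.tsv", hdr)
    truth = {
        "seed": cfg.seed,
        "traits": {name: dataclasses.asdict(spec) for name, spec in traits.items()},
        "coupling": {
            "causal_species": list(coupling_report["causal_species"]),
            "effect_sizes": [float(e) for e in coupling.effect_sizes],
            "noise_sd": float(coupling.noise_sd),
            "r2": float(coupling_report["r2"]),
        },
        "batch_scales": list(cfg.batch_scales),
        "censor_quantile": cfg.censor_quantile,
        "family_rho": cfg.family_rho,
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    return {"matrix": matrix, "profile": profile, "meta": meta}


def _load_inputs(cfg: RunConfig) -> dict:
    if not (cfg.metabolites_path and cfg.metadata_path):
        raise ValueError("metabolites_path and metadata_path required when simulate=false")
    meta = read_metadata(cfg.metadata_path)
    vals = read_matrix(cfg.metabolites_path)
    vals = vals.loc[meta["sample_id"]]
    matrix = MetaboliteMatrix(
        values=vals,
        batch_labels=pd.Series(meta["batch"].to_numpy(), index=vals.index),
    )
    profile = None
    if cfg.microbiome_path:
        prof = read_matrix(cfg.microbiome_path).loc[meta["sample_id"]]
        profile = MicrobiomeProfile(prof)
    return {"matrix": matrix, "profile": profile, "meta": meta}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the report dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "versions": _versions(),
        "stages": {},
    }

    stage = "simulate"
    try:
        if cfg.simulate:
            data = simulate_dataset(cfg, out)
        else:
            data = _load_inputs(cfg)
        matrix, profile, meta = data["matrix"], data["profile"], data["meta"]
        report["stages"]["inputs"] = {
            "n_samples": int(matrix.values.shape[0]),
            "n_metabolites": int(matrix.values.shape[1]),
            "n_species": int(profile.abundances.shape[1]) if profile is not None else 0,
        }
        checksums = {
            p.name: sha256_of(p)
            for p in sorted(out.glob("*.tsv"))
            if p.name in ("metabolites_raw.tsv", "microbiome.tsv", "metadata.tsv")
        }
        hdr = {"seed": cfg.seed, "twinbile_version": __version__, **{
            f"checksum_{k}": v for k, v in checksums.items()
        }}

        stage = "preprocess"
        logger.info("preprocessing %d metabolites", matrix.values.shape[1])
        norm = run_preprocessing(matrix, cfg.max_missing, cfg.int_offset)
        write_matrix(norm.values, out / "metabolites_normalized.tsv", hdr)
        report["stages"]["preprocess"] = {
            "n_kept": int(norm.values.shape[1]),
            "dropped": norm.log[0]["dropped"],
            "n_imputed": norm.log[2]["n_imputed"],
        }

        cohort_df = meta.merge(
            norm.values, left_on="sample_id", right_index=True, how="inner"
        )
        traits = list(norm.values.columns)

        if cfg.run_heritability:
            stage = "heritability"
            logger.info("fitting twin models for %d traits", len(traits))
            cohort = TwinCohort(cohort_df)
            htab = heritability_table(cohort, traits, seed=cfg.seed)
            write_table(htab, out / "heritability.tsv", hdr)
            report["stages"]["heritability"] = {
                "n_traits": len(traits),
                "best_models": dict(zip(htab["trait"], htab["best_model"])),
            }

        if cfg.run_predict and profile is not None:
            stage = "predict"
            filtered, dropped = filter_near_zero_variance(profile)
            logger.info("prediction on %d species (%d dropped)",
                        filtered.abundances.shape[1], len(dropped))
            rows = []
            for i, trait in enumerate(traits):
                perf = predict_metabolite(
                    filtered,
                    meta,
                    cohort_df[trait].to_numpy(),
                    name=trait,
                    k=cfg.k_folds,
                    ntree=cfg.ntree,
                    seed=cfg.seed + 100 + i,  # per-metabolite refolding
                )
                rows.append(
                    {
                        "metabolite": trait,
                        "mean_rho": perf.mean_rho,
                        "rho_lo": perf.ci_rho[0] if perf.ci_rho else np.nan,
                        "rho_hi": perf.ci_rho[1] if perf.ci_rho else np.nan,
                        "mean_auc": perf.mean_auc,
                        "auc_lo": perf.ci_auc[0] if perf.ci_auc else np.nan,
                        "auc_hi": perf.ci_auc[1] if perf.ci_auc else np.nan,
                    }
                )
            ptab = pd.DataFrame(rows)
            write_table(ptab, out / "prediction_performance.tsv", hdr)
            report["stages"]["predict"] = {
                "n_species_dropped": len(dropped),
                "k_folds": cfg.k_folds,
                "ntree": cfg.ntree,
            }

        if cfg.run_associate and profile is not None:
            stage = "associate"
            focal = cfg.coupled_trait if cfg.coupled_trait in traits else traits[-1]
            covs = meta[[c for c in ("age", "bmi", "sex") if c in meta.columns]]
            screen = species_screen(
                profile,
                cohort_df[focal].to_numpy(),
                covariates=covs,
                prevalence=cfg.prevalence,
                outcome=focal,
                cohort=str(meta["cohort"].iloc[0]) if "cohort" in meta.columns else "",
            )
            screen = screen.sort_values("p", kind="stable").reset_index(drop=True)
            write_table(screen, out / "species_screen.tsv", hdr)
            report["stages"]["associate"] = {
                "focal_metabolite": focal,
                "n_species_tested": int(len(screen)),
                "n_significant": int((screen["q"] < cfg.q_threshold).sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (Path(cfg.out_dir) / "run_report.yaml").write_text(
        yaml.safe_dump(report, sort_keys=True)
    )
    return report


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "twinbile": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
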