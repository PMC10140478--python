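"""Metabolite matrix QC and normalization.

Implements the standard delivered-data cleaning chain for untargeted
metabolomics panels measured in instrument batches:

1. drop metabolites with excessive missingness,
2. divide each (metabolite, batch) block by its within-batch median so
   every batch has median 1 (removes multiplicative inter-day batch
   effects),
3. impute remaining missing values with the metabolite's global minimum
   (appropriate under detection-limit left-censoring),
4. map each metabolite onto Gaussian quantiles with a rank-based inverse
   normal transform.

The stages are order-fixed: raw -> scaled -> imputed -> normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteMatrix",
    "filter_missingness",
    "batch_median_scale",
    "impute_minimum",
    "inverse_normal_transform",
    "normalize_matrix",
    "run_preprocessing",
]

_STAGES = ("raw", "scaled", "imputed", "normalized")

# rank offsets for the inverse normal transform: z_i = qnorm((r_i - c) / (n - 2c + 1))
_INT_OFFSETS = {"blom": 3.0 / 8.0, "tukey": 1.0 / 3.0, "waerden": 0.0}


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundance matrix with batch labels.

    ``values`` holds one row per sample and one column per metabolite;
    missing measurements are NaN. ``batch_labels`` is aligned to the rows.
    ``stage`` records how far through the QC chain the matrix has moved.
    """

    values: pd.DataFrame
    batch_labels: pd.Series
    stage: str = "raw"
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.batch_labels) != self.values.shape[0]:
            raise ValueError(
                f"batch_labels length {len(self.batch_labels)} != "
                f"sample count {self.values.shape[0]}"
            )
        self.batch_labels = pd.Series(
            np.asarray(self.batch_labels), index=self.values.index
        )

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def _advance(self, values: pd.DataFrame, stage: str, note: str) -> "MetaboliteMatrix":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(f"cannot move from stage {self.stage!r} back to {stage!r}")
        return replace(self, values=values, stage=stage, log=self.log + [note])


def filter_missingness(m: MetaboliteMatrix, threshold: float = 0.20) -> MetaboliteMatrix:
    """Drop metabolites whose missing fraction strictly exceeds ``threshold``.

    A metabolite missing in exactly ``threshold`` of samples is retained
    (the exclusion rule is strict). Dropped names and their missing
    fractions are appended to the matrix log.
    """
    if m.stage != "raw":
        raise ValueError("missingness filter applies to raw matrices")
    frac = m.values.isna().mean(axis=0)
    dropped = frac[frac > threshold]
    if len(dropped) == len(frac) and len(frac) > 0:
        warnings.warn("all metabolites exceed the missingness threshold", stacklevel=2)
    kept = m.values.loc[:, frac.index[frac <= threshold]]
    note = {
        "op": "filter_missingness",
        "threshold": threshold,
        "dropped": {name: float(f) for name, f in dropped.items()},
    }
    return m._advance(kept, "raw", note)


def batch_median_scale(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each (metabolite, batch) block by its within-batch median.

    After scaling, the median of the observed values in every batch is
    exactly 1 for every metabolite; missing entries stay missing. A batch
    with no observed value, or with median 0, for some metabolite is an
    error (the rescaling is undefined).
    """
    if m.stage not in ("raw", "scaled"):  # idempotent: rescaling scaled data is a no-op
        raise ValueError("batch scaling applies before imputation")
    out = m.values.copy()
    for batch, idx in m.values.groupby(m.batch_labels).groups.items():
        block = m.values.loc[idx]
        med = block.median(axis=0, skipna=True)
        n_obs = block.notna().sum(axis=0)
        empty = med.index[n_obs == 0]
        if len(empty):
            raise ValueError(
                f"metabolite {empty[0]!r} has no observed value in batch {batch!r}"
            )
        zero = med.index[med == 0]
        if len(zero):
            raise ValueError(
                f"metabolite {zero[0]!r} has within-batch median 0 in batch {batch!r}"
            )
        out.loc[idx] = block / med
    return m._advance(out, "scaled", {"op": "batch_median_scale"})


def impute_minimum(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace missing entries with the metabolite's minimum observed value.

    The minimum is taken across all samples and batches of the scaled
    matrix, matching detection-limit censoring: an unobserved value is
    assumed to sit at or below the lowest quantified one.
    """
    if m.stage != "scaled":
        raise ValueError("minimum imputation applies to batch-scaled matrices")
    all_missing = m.values.columns[m.values.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"metabolite {all_missing[0]!r} has no observed values")
    n_imputed = int(m.values.isna().to_numpy().sum())
    out = m.values.fillna(m.values.min(axis=0))
    return m._advance(out, "imputed", {"op": "impute_minimum", "n_imputed": n_imputed})


def inverse_normal_transform(
    v: np.ndarray, offset: float | str = "blom"
) -> np.ndarray:
    """Rank-based inverse normal transform of a complete vector.

    Maps value i to ``Phi^-1((r_i - c) / (n - 2c + 1))`` where r_i is its
    average rank (ties share the mean rank) and c is the rank offset.
    The default Blom offset c = 3/8 gives ``(r - 3/8) / (n + 1/4)``.
    """
    c = _INT_OFFSETS[offset] if isinstance(offset, str) else float(offset)
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if v.size < 2:
        raise ValueError("inverse normal transform needs at least 2 values")
    if np.isnan(v).any():
        raise ValueError("missing values must be imputed before transformation")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - c) / (v.size - 2 * c + 1))


def normalize_matrix(m: MetaboliteMatrix, offset: float | str = "blom") -> MetaboliteMatrix:
    """Apply the inverse normal transform column-wise to an imputed matrix."""
    if m.stage != "imputed":
        raise ValueError("normalization applies to imputed matrices")
    out = m.values.apply(lambda col: inverse_normal_transform(col.to_numpy(), offset))
    return m._advance(out, "normalized", {"op": "inverse_normal_transform", "offset": offset})


def run_preprocessing(
    m: MetaboliteMatrix,
    max_missing: float = 0.20,
    offset: float | str = "blom",
) -> MetaboliteMatrix:
    """Full order-fixed QC chain: filter -> scale -> impute -> transform."""
    return normalize_matrix(
        impute_minimum(batch_median_scale(filter_missingness(m, max_missing))),
        offset,
    )
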