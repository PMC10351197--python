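"""Metabolite QC and transformation.

Pipeline order is: (1) drop metabolites with too much missingness
(a metabolite with 25% or more missing samples is excluded), (2) impute
remaining missing values with the metabolite's observed minimum — the
platform's left-censoring convention for below-detection-limit peaks —
and (3) apply a rank-based inverse normal transform so every phenotype
entering the mixed model is approximately Gaussian.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_missingness",
    "impute_min",
    "inverse_normal_transform",
    "prepare_metabolites",
]


def filter_missingness(
    table: pd.DataFrame, cutoff: float = 0.25
) -> tuple[pd.DataFrame, list[str]]:
    """Keep metabolites with missing fraction strictly below ``cutoff``.

    ``table`` is samples x metabolites with NaN for missing.  Returns the
    kept table and the list of excluded metabolite ids.  The boundary is
    exclusive: a metabolite missing exactly 25% of samples is dropped at
    the default cutoff.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty metabolite table")
    frac = table.isna().mean(axis=0)
    kept = frac.index[frac < cutoff].tolist()
    excluded = frac.index[frac >= cutoff].tolist()
    return table[kept], excluded


def impute_min(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values with the metabolite's observed minimum."""
    if table.isna().all(axis=0).any():
        bad = table.columns[table.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing metabolites (filter first): {bad}")
    return table.fillna(table.min(axis=0))


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom-type offset.

    Maps value with (average, for ties) rank r among n observations to
    ``Phi^{-1}((r - offset) / (n - 2*offset + 1))``.  NaNs are preserved
    in place; ranks are computed over the non-missing entries only.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("constant input cannot be inverse-normal transformed")
    ranks = stats.rankdata(x[obs], method="average")
    out[obs] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out


def prepare_metabolites(
    table: pd.DataFrame, cutoff: float = 0.25, offset: float = 3.0 / 8.0
) -> tuple[pd.DataFrame, list[str]]:
    """filter -> impute -> transform; returns (prepped table, excluded ids)."""
    kept, excluded = filter_missingness(table, cutoff)
    imputed = impute_min(kept)
    prepped = imputed.apply(lambda col: inverse_normal_transform(col, offset), axis=0)
    return prepped, excluded
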