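"""Admixture mapping genome scan.

For each metabolite a null mixed model is fitted once; each
local-ancestry region is then tested with a joint 2-df Wald test of the
three ancestry dosages (rank-reduced by the sum-to-2 constraint: two
dosage columns are tested, the test being invariant to which ancestry is
taken as reference).  Regions passing the family-wise Bonferroni
threshold get ancestry-specific 1-df follow-up tests (each ancestry
against the others); the driving ancestry is the one with the smallest
p-value, and effect sizes are reported from the driving ancestry's
dosage coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import AncestryDosage, compute_pcs
from .cohort import CohortStructure
from .lmm import AncestryLMM, NullModelFit
from .simulate import ANCESTRIES

__all__ = [
    "ScanThresholds",
    "bonferroni_threshold",
    "build_design",
    "joint_test",
    "ancestry_specific_tests",
    "run_scan",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error control: per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ScanThresholds:
    """Multiplicity bookkeeping for a metabolite x region scan."""

    n_metabolites: int
    n_regions: int
    alpha: float = 0.05

    @property
    def genome_wide(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_metabolites * self.n_regions)

    def describe(self) -> str:
        t = self.genome_wide
        return (f"alpha={self.alpha} over {self.n_metabolites} metabolites x "
                f"{self.n_regions} regions -> threshold {t:.3g}")


def build_design(
    covariates: pd.DataFrame,
    covariate_mode: str = "five_pcs",
    pcs: np.ndarray | None = None,
    global_ancestry: pd.DataFrame | None = None,
    genotypes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fixed-effect design: intercept, covariates, and structure adjustment.

    Numeric covariate columns enter as-is; categoricals are dummy-coded
    (first level dropped).  ``covariate_mode`` selects the population
    structure adjustment: ``five_pcs`` (genotype PCs, computed from
    ``genotypes`` if not supplied) or ``global_ancestry`` (two of the
    three genome-wide ancestry proportions; the third is collinear).
    """
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True).astype(float)
            parts.extend(dummies[c] for c in dummies.columns)
    if covariate_mode == "five_pcs":
        if pcs is None:
            if genotypes is None:
                raise ValueError("five_pcs mode needs pcs or genotypes")
            pcs = compute_pcs(genotypes, k=5)
        for j in range(pcs.shape[1]):
            parts.append(pd.Series(pcs[:, j], index=covariates.index,
                                   name=f"PC{j + 1}"))
    elif covariate_mode == "global_ancestry":
        if global_ancestry is None:
            raise ValueError("global_ancestry mode needs proportions")
        if global_ancestry.index.equals(covariates.index):
            ga = global_ancestry
        elif len(global_ancestry) == len(covariates):
            ga = global_ancestry  # positional alignment (same cohort order)
        else:
            ga = global_ancestry.loc[covariates.index.astype(str)]
        parts.append(pd.Series(ga["p_AFR"].to_numpy(), index=covariates.index,
                               name="p_AFR"))
        parts.append(pd.Series(ga["p_NAM"].to_numpy(), index=covariates.index,
                               name="p_NAM"))
    else:
        raise ValueError(f"unknown covariate_mode {covariate_mode!r}")
    return pd.concat(parts, axis=1)


def joint_test(fit: NullModelFit, dosage: np.ndarray,
               extra: np.ndarray | None = None) -> dict:
    """Joint 2-df Wald test of the three ancestry dosages at one region.

    ``dosage`` is (n_samples, 3) summing to 2 per row; the ancestry with
    the largest mean dosage is dropped as the reference (the statistic
    is invariant to the choice).  ``extra`` prepends conditional
    covariates (conditional analyses).  A region where fewer than two
    dosage columns vary is untestable at full rank.
    """
    dosage = np.asarray(dosage, dtype=float)
    ref = int(np.argmax(dosage.mean(axis=0)))
    keep = [a for a in range(3) if a != ref]
    W = dosage[:, keep]
    res = fit.gls_test(W, names=[ANCESTRIES[a] for a in keep], extra=extra)
    return {
        "joint_stat": res.statistic,
        "joint_df": res.df,
        "p_joint": res.pvalue,
        "reference_ancestry": ANCESTRIES[ref],
        "untestable": res.untestable,
        "reduced_df": (not res.untestable) and res.df < 2,
    }


def ancestry_specific_tests(fit: NullModelFit, dosage: np.ndarray,
                            extra: np.ndarray | None = None) -> dict:
    """1-df tests of each ancestry dosage (that ancestry vs the others).

    Returns per-ancestry statistic/p/beta/SE plus the driving ancestry:
    smallest p, ties broken by larger |statistic| then fixed label order.
    A constant dosage column is excluded from the competition.
    """
    dosage = np.asarray(dosage, dtype=float)
    out: dict = {}
    candidates = []
    for a, name in enumerate(ANCESTRIES):
        d = dosage[:, a]
        if d.min() == d.max():
            out[f"stat_{name}"] = np.nan
            out[f"p_{name}"] = np.nan
            out[f"beta_{name}"] = np.nan
            out[f"se_{name}"] = np.nan
            continue
        res = fit.gls_test(d[:, None], names=[name], extra=extra)
        out[f"stat_{name}"] = res.statistic
        out[f"p_{name}"] = res.pvalue
        out[f"beta_{name}"] = res.params[0]
        out[f"se_{name}"] = res.bse[0]
        if not res.untestable:
            candidates.append((res.pvalue, -abs(res.statistic), a))
    if candidates:
        _, _, a = min(candidates)
        name = ANCESTRIES[a]
        out["driving_ancestry"] = name
        out["beta_driving"] = out[f"beta_{name}"]
        out["se_driving"] = out[f"se_{name}"]
    else:
        out["driving_ancestry"] = None
        out["beta_driving"] = np.nan
        out["se_driving"] = np.nan
    return out


def fit_null_models(
    phenotypes: pd.DataFrame, design: pd.DataFrame, structure: CohortStructure,
) -> dict[str, NullModelFit]:
    """One REML null fit per metabolite (components reused by all tests)."""
    fits = {}
    for met in phenotypes.columns:
        fit = AncestryLMM(phenotypes[met].to_numpy(), design, structure).fit()
        if not fit.converged:
            continue  # downstream refuses to test an unconverged fit
        fits[met] = fit
    return fits


def run_scan(
    phenotypes: pd.DataFrame,
    dosages: AncestryDosage,
    structure: CohortStructure,
    design: pd.DataFrame,
    thresholds: ScanThresholds | None = None,
    ancestry_tests: str = "significant",
    null_fits: dict | None = None,
) -> pd.DataFrame:
    """Scan every metabolite x region pair; returns the association table.

    ``ancestry_tests`` is ``"significant"`` (follow-up only below the
    genome-wide threshold, as in a production scan) or ``"always"``.
    Output rows are ordered by metabolite id then genomic region order.
    """
    if thresholds is None:
        thresholds = ScanThresholds(
            n_metabolites=max(1, phenotypes.shape[1]),
            n_regions=max(1, dosages.n_regions),
        )
    gate = thresholds.genome_wide
    if null_fits is None:
        null_fits = fit_null_models(phenotypes, design, structure)
    records = []
    for met in sorted(phenotypes.columns):
        fit = null_fits.get(met)
        if fit is None:
            continue
        for row in dosages.regions.itertuples(index=False):
            rid = int(row.region_id)
            d = dosages.region_dosage(rid)
            rec = {"metabolite": met, "region_id": rid, "chrom": row.chrom}
            rec.update(joint_test(fit, d))
            significant = (not rec["untestable"]) and rec["p_joint"] < gate
            rec["significant"] = significant
            if ancestry_tests == "always" or significant:
                rec.update(ancestry_specific_tests(fit, d))
            records.append(rec)
    out = pd.DataFrame(records)
    out.attrs["threshold"] = gate
    if len(out):
        sig = out[out["significant"]]
        out.attrs["summary"] = {
            "n_significant_pairs": int(len(sig)),
            "n_significant_regions": int(sig["region_id"].nunique()),
            "n_significant_metabolites": int(sig["metabolite"].nunique()),
            "threshold": gate,
        }
    else:
        out.attrs["summary"] = {
            "n_significant_pairs": 0, "n_significant_regions": 0,
            "n_significant_metabolites": 0, "threshold": gate,
        }
    return out
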