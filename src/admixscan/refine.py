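"""Post-scan refinement of admixture mapping signals.

Four stages follow the genome scan:

* **Conditional region analysis** — neighboring significant regions share
  long-range admixture-LD (tracts average > 6 cM), so each significant
  region within 10 cM of the most significant ("anchor") region is
  re-tested with the anchor's driving-ancestry dosage as a covariate;
  only regions keeping a joint p < 5e-5 are declared independent.  The
  procedure iterates anchors in descending significance.
* **SNV fine-mapping** — SNVs inside an independent region are tested
  with the same mixed model; mutually independent SNVs are chosen by
  exact individual-level forward stepwise selection at the genome-wide
  SNV threshold 5e-8 (the conditional-and-joint selection target,
  computed on individual-level data rather than summary statistics).
* **SNV conditioning** — the admixture joint test is re-run with each
  selected SNV's allele count as a covariate; a region's signal is
  "explained" by a SNV when the conditional joint p rises above 5e-5.
  If no single SNV explains it, all selected SNVs enter jointly.
* **Novelty / replication** — regions with no overlapping known
  significant variant are flagged novel; replication re-runs the tests
  in an independent cohort under a Bonferroni threshold and checks
  direction-of-effect and driving-ancestry concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import AncestryDosage
from .lmm import NullModelFit
from .scan import ancestry_specific_tests, bonferroni_threshold, joint_test
from .simulate import ANCESTRIES

__all__ = [
    "conditional_region_scan",
    "snv_scan",
    "stepwise_select",
    "condition_admixture_on_snvs",
    "SnvConditioningResult",
    "flag_novel",
    "read_known_hits",
    "replicate",
]

ANC_INDEX = {a: i for i, a in enumerate(ANCESTRIES)}


def _region_midpoints(regions: pd.DataFrame) -> pd.Series:
    mid = 0.5 * (regions["start_cM"] + regions["end_cM"])
    return pd.Series(mid.to_numpy(), index=regions["region_id"].to_numpy())


def conditional_region_scan(
    records: pd.DataFrame,
    dosages: AncestryDosage,
    null_fits: dict[str, NullModelFit],
    window_cm: float = 10.0,
    keep_threshold: float = 5e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve neighboring significant regions into independent signals.

    Per metabolite, the smallest-p significant region anchors; every
    other surviving significant region whose midpoint lies within
    ``window_cm`` of the anchor (same chromosome) is re-tested with the
    anchor's driving-ancestry dosage added to the fixed effects and kept
    only if the conditional joint p stays below ``keep_threshold``.
    Surviving regions anchor in turn until no unresolved pair remains.

    Returns ``(conditional_results, independent_regions)``.
    """
    mid = _region_midpoints(dosages.regions)
    chrom = pd.Series(dosages.regions["chrom"].to_numpy(),
                      index=dosages.regions["region_id"].to_numpy())
    results = []
    independent = []
    sig = records[records.get("significant", False) == True]  # noqa: E712
    for met, sub in sig.groupby("metabolite", sort=True):
        fit = null_fits[met]
        queue = sub.sort_values(["p_joint", "region_id"]).to_dict("records")
        while queue:
            anchor = queue.pop(0)
            aid = int(anchor["region_id"])
            independent.append({
                "metabolite": met, "region_id": aid,
                "p_joint": anchor["p_joint"],
                "driving_ancestry": anchor.get("driving_ancestry"),
                "beta_driving": anchor.get("beta_driving"),
                "se_driving": anchor.get("se_driving"),
            })
            results.append({
                "metabolite": met, "region_id": aid, "anchor_id": aid,
                "conditioned_on": "none (anchor)",
                "p_before": anchor["p_joint"], "p_after": anchor["p_joint"],
                "kept": True, "collinear": False,
            })
            drv = anchor.get("driving_ancestry")
            if drv is None or (isinstance(drv, float) and np.isnan(drv)):
                continue
            cond = dosages.region_dosage(aid)[:, ANC_INDEX[drv]][:, None]
            survivors = []
            for other in queue:
                rid = int(other["region_id"])
                near = (chrom[rid] == chrom[aid]
                        and abs(mid[rid] - mid[aid]) <= window_cm)
                if not near:
                    survivors.append(other)
                    continue
                jt = joint_test(fit, dosages.region_dosage(rid), extra=cond)
                collinear = jt["untestable"]
                kept = (not collinear) and jt["p_joint"] < keep_threshold
                results.append({
                    "metabolite": met, "region_id": rid, "anchor_id": aid,
                    "conditioned_on": f"{drv} dosage at region {aid}",
                    "p_before": other["p_joint"],
                    "p_after": np.nan if collinear else jt["p_joint"],
                    "kept": kept, "collinear": collinear,
                })
                if kept:
                    survivors.append(other)
            queue = survivors
    cols = ["metabolite", "region_id", "anchor_id", "conditioned_on",
            "p_before", "p_after", "kept", "collinear"]
    icols = ["metabolite", "region_id", "p_joint", "driving_ancestry",
             "beta_driving", "se_driving"]
    return (pd.DataFrame(results, columns=cols),
            pd.DataFrame(independent, columns=icols))


# ---------------------------------------------------------------------------
# SNV association and stepwise selection
# ---------------------------------------------------------------------------


def snv_scan(fit: NullModelFit, genotypes: np.ndarray, snv_ids) -> pd.DataFrame:
    """Single-SNV mixed-model association (1-df Wald per allele count).

    ``genotypes`` is (n_snvs, n_samples).  Monomorphic SNVs are skipped.
    """
    rows = []
    for j, sid in enumerate(snv_ids):
        g = np.asarray(genotypes[j], dtype=float)
        if g.min() == g.max():
            continue
        res = fit.gls_test(g[:, None], names=[str(sid)])
        if res.untestable:
            continue
        rows.append({"snv_id": sid, "beta": res.params[0], "se": res.bse[0],
                     "stat": res.statistic, "p": res.pvalue})
    return pd.DataFrame(rows, columns=["snv_id", "beta", "se", "stat", "p"])


def _r2_with_set(g: np.ndarray, G_sel: np.ndarray) -> float:
    """R^2 of a candidate genotype regressed on the selected set."""
    X = np.column_stack([np.ones(len(g)), G_sel.T])
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ coef
    tot = float(((g - g.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / tot if tot > 0 else 1.0


def stepwise_select(
    fit: NullModelFit,
    genotypes: np.ndarray,
    snv_ids,
    entry_p: float = 5e-8,
    r2_max: float = 0.99,
) -> pd.DataFrame:
    """Forward-stepwise selection of mutually independent associated SNVs.

    Start from the smallest marginal-p SNV; repeatedly add the candidate
    with the smallest conditional p (given the selected set as fixed
    covariates) while that p < ``entry_p``, skipping candidates in near
    collinearity (R^2 > ``r2_max``) with the selected set.  A final
    joint model prunes (one backward pass) any selected SNV whose
    conditional-on-the-rest p exceeds ``entry_p``.  Returns the selected
    SNVs with their joint-model coefficients and p-values.
    """
    snv_ids = list(snv_ids)
    marginal = snv_scan(fit, genotypes, snv_ids)
    empty = pd.DataFrame(columns=["snv_id", "beta", "se", "p_conditional"])
    if len(marginal) == 0 or marginal["p"].min() >= entry_p:
        return empty
    id_to_row = {sid: j for j, sid in enumerate(snv_ids)}
    selected = [marginal.loc[marginal["p"].idxmin(), "snv_id"]]
    while True:
        G_sel = genotypes[[id_to_row[s] for s in selected]].astype(float)
        best = None
        for sid in marginal["snv_id"]:
            if sid in selected:
                continue
            g = genotypes[id_to_row[sid]].astype(float)
            if _r2_with_set(g, G_sel) > r2_max:
                continue
            res = fit.gls_test(g[:, None], names=[str(sid)], extra=G_sel.T)
            if res.untestable:
                continue
            if best is None or res.pvalue < best[1]:
                best = (sid, res.pvalue)
        if best is None or best[1] >= entry_p:
            break
        selected.append(best[0])
    # backward pass on the joint model
    rows = []
    keep = []
    for sid in selected:
        others = [s for s in selected if s != sid]
        extra = (genotypes[[id_to_row[s] for s in others]].astype(float).T
                 if others else None)
        g = genotypes[id_to_row[sid]].astype(float)
        res = fit.gls_test(g[:, None], names=[str(sid)], extra=extra)
        if res.pvalue < entry_p:
            keep.append(sid)
            rows.append({"snv_id": sid, "beta": res.params[0],
                         "se": res.bse[0], "p_conditional": res.pvalue})
    return pd.DataFrame(rows, columns=empty.columns) if rows else empty


@dataclass
class SnvConditioningResult:
    """Outcome of conditioning an admixture signal on its selected SNVs."""

    metabolite: str
    region_id: int
    snv_ids: list
    p_unconditional: float
    p_conditional_per_snv: dict = field(default_factory=dict)
    p_conditional_joint_set: float | None = None
    decision: str = "not_explained"  # explained_by_single | explained_by_set
    explaining_snv: str | None = None

    @property
    def explained(self) -> bool:
        return self.decision.startswith("explained")


def condition_admixture_on_snvs(
    fit: NullModelFit,
    region_dosage: np.ndarray,
    genotypes: np.ndarray,
    snv_ids,
    explain_threshold: float = 5e-5,
    metabolite: str = "",
    region_id: int = -1,
) -> SnvConditioningResult:
    """Attribute an admixture signal to selected SNVs by conditioning.

    Each SNV enters singly as a fixed covariate of the joint admixture
    test; the signal is ``explained_by_single`` if any conditional joint
    p rises above ``explain_threshold``.  Otherwise all SNVs enter one
    joint conditional model (``explained_by_set`` if that p rises above
    the threshold), else ``not_explained``.
    """
    snv_ids = list(snv_ids)
    if not snv_ids:
        raise ValueError("nonempty SNV set required")
    base = joint_test(fit, region_dosage)
    out = SnvConditioningResult(
        metabolite=metabolite, region_id=region_id, snv_ids=snv_ids,
        p_unconditional=base["p_joint"],
    )
    best = None
    for j, sid in enumerate(snv_ids):
        g = np.asarray(genotypes[j], dtype=float)[:, None]
        jt = joint_test(fit, region_dosage, extra=g)
        p = np.nan if jt["untestable"] else jt["p_joint"]
        out.p_conditional_per_snv[sid] = p
        if not jt["untestable"] and p > explain_threshold:
            if best is None or p > best[1]:
                best = (sid, p)
    if best is not None:
        out.decision = "explained_by_single"
        out.explaining_snv = best[0]
        return out
    if len(snv_ids) > 1:
        G = np.asarray(genotypes, dtype=float).T
        jt = joint_test(fit, region_dosage, extra=G)
        out.p_conditional_joint_set = np.nan if jt["untestable"] else jt["p_joint"]
        if not jt["untestable"] and out.p_conditional_joint_set > explain_threshold:
            out.decision = "explained_by_set"
    return out


# ---------------------------------------------------------------------------
# novelty and replication
# ---------------------------------------------------------------------------


def read_known_hits(path) -> pd.DataFrame:
    """Known significant variants: 2-column (chrom, bp) TSV or 3-column BED.

    Returns 1-based half-open intervals (chrom, start, end); a point hit
    at bp becomes [bp, bp+1).  BED input (0-based half-open) is shifted
    to 1-based.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: malformed known-hits file")
    first = df.iloc[0]
    if isinstance(first[1], str) and not str(first[1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)  # header row
    if df.shape[1] == 2:
        bp = df[1].astype(np.int64)
        out = pd.DataFrame({"chrom": df[0].astype(str), "start": bp, "end": bp + 1})
    else:
        out = pd.DataFrame({
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64) + 1,
            "end": df[2].astype(np.int64) + 1,
        })
    if (out["end"] <= out["start"]).any():
        raise ValueError(f"{path}: empty or inverted interval")
    return out


def flag_novel(regions: pd.DataFrame, known_hits: pd.DataFrame) -> pd.Series:
    """True where no known hit overlaps the region [start_bp, end_bp)."""
    novel = np.ones(len(regions), dtype=bool)
    for i, row in enumerate(regions.itertuples(index=False)):
        hits = known_hits[known_hits["chrom"].astype(str) == str(row.chrom)]
        overlap = ((hits["start"] < row.end_bp) & (hits["end"] > row.start_bp)).any()
        novel[i] = not overlap
    return pd.Series(novel, index=regions.index, name="novel")


def replicate(
    discovery: pd.DataFrame,
    rep_phenotypes: pd.DataFrame,
    rep_dosages: AncestryDosage,
    rep_null_fits: dict[str, NullModelFit],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Re-test discovery-independent associations in a replication cohort.

    ``discovery`` rows carry metabolite, region_id, driving_ancestry and
    beta_driving.  The replication threshold is ``alpha / n_tests``
    (n_tests defaults to the number of discovery associations).
    Reports, per association: the replication joint p, replicated flag,
    sign concordance of the discovery driving ancestry's effect, and
    driving-ancestry concordance.
    """
    rows = list(discovery.itertuples(index=False))
    testable = [r for r in rows if r.metabolite in rep_null_fits]
    if n_tests is None:
        n_tests = len(rows)
    thr = bonferroni_threshold(alpha, n_tests)
    out = []
    for r in testable:
        fit = rep_null_fits[r.metabolite]
        d = rep_dosages.region_dosage(int(r.region_id))
        jt = joint_test(fit, d)
        at = ancestry_specific_tests(fit, d)
        rec = {
            "metabolite": r.metabolite, "region_id": int(r.region_id),
            "p_joint_replication": jt["p_joint"],
            "replicated": (not jt["untestable"]) and jt["p_joint"] < thr,
            "driving_ancestry_discovery": r.driving_ancestry,
            "driving_ancestry_replication": at["driving_ancestry"],
            "driving_concordant": at["driving_ancestry"] == r.driving_ancestry,
        }
        beta_rep = at.get(f"beta_{r.driving_ancestry}", np.nan)
        rec["beta_replication"] = beta_rep
        rec["sign_concordant"] = bool(
            np.isfinite(beta_rep) and np.sign(beta_rep) == np.sign(r.beta_driving)
        )
        out.append(rec)
    res = pd.DataFrame(out)
    res.attrs["threshold"] = thr
    res.attrs["n_tests"] = n_tests
    return res
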