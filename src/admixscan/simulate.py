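"""Synthetic admixed cohorts for admixture mapping.

The generator produces every input the analysis consumes, with the
statistical properties the method relies on:

* three-way (African / European / Native American) local-ancestry tracts
  from admixture ~15 generations ago, so mean tract length is
  100/g ≈ 6.7 cM and neighboring regions share long-range admixture-LD;
* two sampling groups with different mean admixture proportions
  (a mainland-like group with more Native American ancestry, a
  caribbean-like group with more African ancestry);
* genotypes whose allele frequencies differ by tract ancestry;
* metabolite-like phenotypes with kinship, household and census-block
  random effects, fixed covariates (age, sex, an eGFR-like measure,
  recruitment center, group), optional causal ancestry and SNV effects,
  and missing-at-random entries.

The tract model is a Poisson switch process: ancestry switch points fall
at rate g per Morgan along each haplotype and each tract's ancestry is
drawn independently from the individual's admixture proportion vector.
This reproduces the two features the analysis exploits — the tract-length
scale and the decay of admixture-LD — without a pedigree simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import CohortStructure
from .genmap import GeneticMap, build_regions

__all__ = [
    "ANCESTRIES",
    "SimConfig",
    "TractSet",
    "simulate_structure",
    "simulate_proportions",
    "simulate_tracts",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_cohort",
]

ANCESTRIES = ("AFR", "EUR", "NAM")

# group-level mean admixture proportions (AFR, EUR, NAM)
DEFAULT_GROUPS = {
    "mainland": (0.10, 0.45, 0.45),
    "caribbean": (0.35, 0.50, 0.15),
}


@dataclass
class SimConfig:
    """All knobs of the cohort generator.

    Defaults describe the study conditions the package targets: admixture
    g = 15 generations ago, two sampling groups with distinct three-way
    admixture, family/household/block clustering, and metabolite
    phenotypes dominated by residual variance with a ~30% genetic
    component.
    """

    n_samples: int = 1000
    generations: float = 15.0
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    group_weights: dict = field(
        default_factory=lambda: {"mainland": 0.6, "caribbean": 0.4}
    )
    dirichlet_concentration: float = 30.0
    # map / regions / SNVs
    n_chrom: int = 1
    chrom_length_cm: float = 100.0
    n_regions: int = 50
    n_snvs: int = 0
    snv_freqs: np.ndarray | None = None  # (n_snvs, 3) per-ancestry frequencies
    # family / household / block structure
    sib_pair_fraction: float = 0.1
    household_size: int = 4
    households_per_block: int = 4
    # phenotype model
    n_metabolites: int = 1
    sigma_g: float = 0.30
    sigma_h: float = 0.10
    sigma_c: float = 0.05
    sigma_e: float = 0.55
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_egfr: float = 0.0
    # causal effects: lists of (region_id, ancestry_name, beta) / (snv_index, beta)
    ancestry_effects: list = field(default_factory=list)
    snv_effects: list = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.groups.items():
            p = np.asarray(p, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"group {name}: proportions must be a simplex vector")
        for s in ("sigma_g", "sigma_h", "sigma_c", "sigma_e"):
            if getattr(self, s) < 0:
                raise ValueError(f"{s} must be >= 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_sib_pairs(self) -> int:
        return int(round(self.sib_pair_fraction * self.n_samples / 2))


# ---------------------------------------------------------------------------
# tracts
# ---------------------------------------------------------------------------


@dataclass
class TractSet:
    """Per-haplotype ancestry tracts tiling each chromosome in cM.

    ``tracts[chrom]`` is a list over haplotypes (2 per sample, sample-major:
    haplotype ``2*i + j`` is haplotype ``j`` of sample ``i``) of
    ``(ends_cM, ancestry)`` pairs: tract k covers
    ``[start_k, ends_cM[k])`` with ``start_0`` the chromosome's cM origin.
    """

    sample_ids: np.ndarray
    genmap: GeneticMap
    tracts: dict
    proportions: np.ndarray  # (n_samples, 3) individual admixture proportions

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def ancestry_at(self, chrom: str, cm_pos: np.ndarray) -> np.ndarray:
        """Ancestry codes (0=AFR,1=EUR,2=NAM), shape (2*n_samples, n_pos)."""
        cm_pos = np.asarray(cm_pos, dtype=float)
        haps = self.tracts[str(chrom)]
        out = np.empty((len(haps), len(cm_pos)), dtype=np.int8)
        for h, (ends, anc) in enumerate(haps):
            idx = np.searchsorted(ends, cm_pos, side="right")
            idx = np.minimum(idx, len(anc) - 1)  # chromosome end belongs to last tract
            out[h] = anc[idx]
        return out

    def tract_lengths(self) -> np.ndarray:
        """All tract lengths in cM, concatenated over haplotypes/chromosomes."""
        lengths = []
        for chrom, haps in self.tracts.items():
            lo, _ = self.genmap.cm_span(chrom)
            for ends, _anc in haps:
                starts = np.concatenate(([lo], ends[:-1]))
                lengths.append(ends - starts)
        return np.concatenate(lengths)

    def realized_fractions(self) -> np.ndarray:
        """Genome-wide realized ancestry fraction per sample, (n_samples, 3)."""
        n = self.n_samples
        tot = np.zeros((n, 3))
        for chrom, haps in self.tracts.items():
            lo, _ = self.genmap.cm_span(chrom)
            for h, (ends, anc) in enumerate(haps):
                starts = np.concatenate(([lo], ends[:-1]))
                L = ends - starts
                for a in range(3):
                    tot[h // 2, a] += L[anc == a].sum()
        return tot / tot.sum(axis=1, keepdims=True)

    def rasterize(self, regions: pd.DataFrame):
        """Local-ancestry calls on a region grid (ancestry at region midpoint)."""
        from .ancestry import LocalAncestryCalls

        codes = np.empty((len(regions), self.n_samples, 2), dtype=np.int8)
        for chrom, sub in regions.groupby("chrom", sort=False):
            mid = 0.5 * (sub["start_cM"].to_numpy() + sub["end_cM"].to_numpy())
            anc = self.ancestry_at(chrom, mid)  # (2n, n_reg_chrom)
            codes[sub.index.to_numpy()] = anc.T.reshape(len(sub), self.n_samples, 2)
        return LocalAncestryCalls(
            regions=regions.reset_index(drop=True),
            sample_ids=self.sample_ids,
            codes=codes,
        )


def simulate_proportions(config: SimConfig, rng: np.random.Generator):
    """Group labels and individual Dirichlet admixture proportions."""
    names = list(config.groups)
    w = np.array([config.group_weights.get(g, 1.0) for g in names], dtype=float)
    w = w / w.sum()
    gidx = rng.choice(len(names), size=config.n_samples, p=w)
    groups = np.array(names, dtype=object)[gidx]
    props = np.empty((config.n_samples, 3))
    for i, g in enumerate(gidx):
        mean = np.asarray(config.groups[names[g]], dtype=float)
        alpha = np.maximum(config.dirichlet_concentration * mean, 1e-9)
        props[i] = rng.dirichlet(alpha)
    return groups, props


def simulate_structure(
    n_samples: int,
    n_sib_pairs: int = 0,
    household_size: int = 4,
    households_per_block: int = 4,
    sibship_size: int = 2,
    sample_ids: np.ndarray | None = None,
) -> CohortStructure:
    """Build kinship + household/block labels from declared relationships.

    The first ``n_sib_pairs * sibship_size`` samples form full sibships
    (kinship 0.25 between every pair of sibs); everyone else is
    unrelated.  Sib pairs (``sibship_size == 2``) share a household;
    larger sibships fill consecutive households, so their kinship is not
    confounded with the household effect.  Households are filled
    sequentially with ``household_size`` members and grouped
    ``households_per_block`` to a census block.
    """
    if household_size < 1 or households_per_block < 1:
        raise ValueError("household_size and households_per_block must be >= 1")
    if sibship_size < 2:
        raise ValueError("sibship_size must be >= 2")
    if sibship_size * n_sib_pairs > n_samples:
        raise ValueError(
            f"{n_sib_pairs} sibships of {sibship_size} need "
            f"{sibship_size * n_sib_pairs} samples, have {n_samples}"
        )
    if n_sib_pairs > 0 and household_size < 2:
        raise ValueError("sib pairs require household_size >= 2")
    if sample_ids is None:
        sample_ids = np.array([f"S{i:05d}" for i in range(n_samples)])

    rows, cols, vals = [], [], []
    for p in range(n_sib_pairs):
        base = sibship_size * p
        for i in range(sibship_size):
            for j in range(sibship_size):
                if i != j:
                    rows.append(base + i)
                    cols.append(base + j)
                    vals.append(0.25)
    rows += list(range(n_samples))
    cols += list(range(n_samples))
    vals += [0.5] * n_samples
    kin = sp.csr_matrix((vals, (rows, cols)), shape=(n_samples, n_samples))

    # sib pairs must share a household: assign households pair-aware
    household = np.empty(n_samples, dtype=object)
    hh, room = 0, household_size
    idx = 0
    n_related = sibship_size * n_sib_pairs
    while idx < n_samples:
        take = 2 if (sibship_size == 2 and idx < n_related) else 1
        if room < take:
            hh, room = hh + 1, household_size
        for k in range(take):
            household[idx + k] = f"H{hh:05d}"
        room -= take
        idx += take
    hh_codes, _ = pd.factorize(household)
    block = np.array([f"B{c // households_per_block:05d}" for c in hh_codes])
    return CohortStructure(sample_ids, kin, household, block)


def simulate_tracts(
    config: SimConfig,
    genmap: GeneticMap,
    rng: np.random.Generator,
    proportions: np.ndarray | None = None,
    sample_ids: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> TractSet:
    """Poisson switch-process ancestry tracts for every haplotype.

    Switch points fall at rate g per Morgan; tract ancestries are iid
    draws from the individual's admixture proportion vector.  g = 0
    yields whole-chromosome tracts.
    """
    if not genmap.chromosomes:
        raise ValueError("empty genetic map")
    if proportions is None:
        groups, proportions = simulate_proportions(config, rng)
    proportions = np.asarray(proportions, dtype=float)
    n = len(proportions)
    if sample_ids is None:
        sample_ids = np.array([f"S{i:05d}" for i in range(n)])
    g = float(config.generations)
    tracts: dict = {}
    for chrom in genmap.chromosomes:
        lo, hi = genmap.cm_span(chrom)
        L_morgan = (hi - lo) / 100.0
        haps = []
        for i in range(n):
            p = proportions[i]
            for _hap in range(2):
                k = rng.poisson(g * L_morgan) if g > 0 else 0
                cuts = np.sort(rng.uniform(lo, hi, size=k))
                ends = np.concatenate((cuts, [hi]))
                # tracts are delimited by switch points; adjacent tracts may
                # repeat an ancestry (mean tract length stays 100/g cM)
                anc = rng.choice(3, size=k + 1, p=p).astype(np.int8)
                haps.append((ends, anc))
        tracts[chrom] = haps
    ts = TractSet(sample_ids=sample_ids, genmap=genmap, tracts=tracts,
                  proportions=proportions)
    ts.groups = groups
    return ts


def simulate_genotypes(
    tracts: TractSet, snv_table: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Allele counts (n_snvs, n_samples) given per-ancestry frequencies.

    ``snv_table`` columns: ``snv_id, chrom, bp, cM, freq_AFR, freq_EUR,
    freq_NAM``.  Each haplotype's allele is Bernoulli with the frequency
    of the ancestry of the tract covering the SNV.
    """
    freqs = snv_table[["freq_AFR", "freq_EUR", "freq_NAM"]].to_numpy(dtype=float)
    if freqs.min() < 0 or freqs.max() > 1:
        raise ValueError("allele frequencies must lie in [0, 1]")
    n = tracts.n_samples
    geno = np.empty((len(snv_table), n), dtype=np.int8)
    for chrom, sub in snv_table.groupby("chrom", sort=False):
        lo, hi = tracts.genmap.cm_span(chrom)
        cm = sub["cM"].to_numpy(dtype=float)
        if np.any(cm < lo) or np.any(cm > hi):
            raise ValueError(f"SNV outside map span of chromosome {chrom}")
        anc = tracts.ancestry_at(chrom, cm)  # (2n, n_snv_chrom)
        f = freqs[sub.index.to_numpy()]  # (n_snv_chrom, 3)
        p_hap = f[np.arange(len(sub))[None, :], anc]  # (2n, n_snv_chrom)
        alleles = rng.random(p_hap.shape) < p_hap
        counts = alleles.reshape(n, 2, len(sub)).sum(axis=1)
        geno[sub.index.to_numpy()] = counts.T.astype(np.int8)
    return geno


def make_snv_table(
    genmap: GeneticMap,
    n_snvs: int,
    freqs: np.ndarray | None,
    rng: np.random.Generator,
    fst: float = 0.12,
) -> pd.DataFrame:
    """Evenly spaced SNVs with supplied or Balding-Nichols frequencies.

    Default per-ancestry frequencies diverge from a shared ancestral
    frequency with differentiation ``fst`` (~continental scale), so
    genome-wide genotypes are ancestry-informative, as the analysis
    assumes of real array data.
    """
    lengths = np.array([genmap.length_cm(c) for c in genmap.chromosomes])
    alloc = np.maximum(1, np.rint(n_snvs * lengths / lengths.sum()).astype(int))
    while alloc.sum() > n_snvs:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_snvs:
        alloc[np.argmax(lengths / alloc)] += 1
    rows = []
    for chrom, k in zip(genmap.chromosomes, alloc):
        lo, hi = genmap.cm_span(chrom)
        cm = np.linspace(lo, hi, k + 2)[1:-1]
        bp = genmap.bp_at(chrom, cm)
        for j in range(k):
            rows.append((f"snv_{chrom}_{j}", chrom, int(bp[j]), float(cm[j])))
    tab = pd.DataFrame(rows, columns=["snv_id", "chrom", "bp", "cM"])
    if freqs is None:
        anc = rng.uniform(0.1, 0.9, size=(n_snvs, 1))
        a = anc * (1 - fst) / fst
        b = (1 - anc) * (1 - fst) / fst
        freqs = np.clip(rng.beta(a, b, size=(n_snvs, 3)), 0.01, 0.99)
    freqs = np.asarray(freqs, dtype=float).reshape(n_snvs, 3)
    tab[["freq_AFR", "freq_EUR", "freq_NAM"]] = freqs
    return tab


def simulate_covariates(
    config: SimConfig, groups: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Age / sex / eGFR-like / center / group covariate table."""
    n = config.n_samples
    age = np.clip(rng.normal(46.0, 14.0, n), 18, 74)
    sex = (rng.random(n) < 0.57).astype(int)  # 1 = female
    egfr = rng.normal(96.0, 16.0, n)
    center = rng.choice(["A", "B", "C", "D"], size=n)
    return pd.DataFrame(
        {"age": age, "sex": sex, "egfr": egfr, "center": center, "group": groups}
    )


def _sample_genetic_effect(
    structure: CohortStructure, sigma_g: float, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws from N(0, sigma_g * 2K), exploiting the block structure of K."""
    n = structure.n_samples
    out = rng.standard_normal((n, n_draws))
    if sigma_g == 0:
        return np.zeros((n, n_draws))
    K2 = (2.0 * structure.kinship).tocsr()
    ncomp, labels = sp.csgraph.connected_components(K2, directed=False)
    for c in range(ncomp):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            out[idx] *= np.sqrt(K2[idx[0], idx[0]])
            continue
        block = K2[np.ix_(idx, idx)].toarray()
        L = np.linalg.cholesky(block)
        out[idx] = L @ out[idx]
    return np.sqrt(sigma_g) * out


def simulate_phenotypes(
    structure: CohortStructure,
    covariates: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    dosages=None,
    genotypes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Metabolite phenotypes: fixed effects + causal loci + 3 random effects.

    y = b0 + age*b_age + sex*b_sex + egfr*b_egfr
        + sum_r beta_r * d_{ancestry_r}(r) + sum_s beta_s * g_s
        + u_g + u_h + u_c + e,
    u_g ~ N(0, sigma_g * 2K), u_h / u_c cluster-level iid normal,
    e iid N(0, sigma_e).  Missing entries (MCAR at ``missing_rate``) are
    encoded as NaN.
    """
    n = structure.n_samples
    if len(covariates) != n:
        raise ValueError("covariate table does not match cohort size")
    m = config.n_metabolites
    anc_index = {a: k for k, a in enumerate(ANCESTRIES)}

    # causal effects: (region, ancestry, beta[, metabolite_index]) and
    # (snv_index, beta[, metabolite_index]); 3-tuples hit every metabolite
    signal = np.zeros((n, m))
    for eff in config.ancestry_effects:
        region_id, ancestry, beta = eff[:3]
        if dosages is None:
            raise ValueError("ancestry_effects given but no dosages")
        d = dosages.values[dosages.region_index(region_id), :, anc_index[ancestry]]
        cols = [eff[3]] if len(eff) > 3 else slice(None)
        signal[:, cols] += (beta * d)[:, None]
    for eff in config.snv_effects:
        snv_idx, beta = eff[:2]
        if genotypes is None:
            raise ValueError("snv_effects given but no genotypes")
        cols = [eff[2]] if len(eff) > 2 else slice(None)
        signal[:, cols] += (beta * genotypes[snv_idx].astype(float))[:, None]

    fixed = (
        config.beta_age * covariates["age"].to_numpy()
        + config.beta_sex * covariates["sex"].to_numpy()
        + config.beta_egfr * covariates["egfr"].to_numpy()
    )

    u_g = _sample_genetic_effect(structure, config.sigma_g, m, rng)
    hh_codes, _ = pd.factorize(structure.household)
    bl_codes, _ = pd.factorize(structure.block)
    u_h = np.sqrt(config.sigma_h) * rng.standard_normal((hh_codes.max() + 1, m))[hh_codes]
    u_c = np.sqrt(config.sigma_c) * rng.standard_normal((bl_codes.max() + 1, m))[bl_codes]
    eps = np.sqrt(config.sigma_e) * rng.standard_normal((n, m))

    Y = fixed[:, None] + signal + u_g + u_h + u_c + eps
    if config.missing_rate > 0:
        Y = Y.copy()
        Y[rng.random(Y.shape) < config.missing_rate] = np.nan
    cols = {f"met_{j:03d}": Y[:, j] for j in range(m)}
    out = pd.DataFrame(cols, index=[str(s) for s in structure.sample_ids])
    out.index.name = "sample"
    return out


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """Everything one simulation run produced, ready for the pipeline."""

    config: SimConfig
    genmap: GeneticMap
    structure: CohortStructure
    tracts: TractSet
    regions: pd.DataFrame
    calls: object  # LocalAncestryCalls
    dosages: object  # AncestryDosage
    snv_table: pd.DataFrame
    genotypes: np.ndarray | None
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame

    def write(self, outdir) -> None:
        """Write every artifact as the plain-text formats the CLI reads."""
        from pathlib import Path

        from .ancestry import write_genotype_tsv, write_local_ancestry

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genmap.to_tsv(out / "map.tsv")
        self.structure.write(out / "kinship.tsv", out / "clusters.tsv")
        write_local_ancestry(self.calls, out / "local_ancestry.tsv")
        self.covariates.rename_axis("sample").to_csv(
            out / "covariates.tsv", sep="\t")
        self.phenotypes.to_csv(out / "metabolites.tsv", sep="\t")
        if self.genotypes is not None:
            write_genotype_tsv(
                self.snv_table, self.genotypes, self.structure.sample_ids,
                out / "genotypes.tsv",
            )


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimulatedCohort:
    """Run the full generator under one seed (the seed fully determines output)."""
    from .ancestry import dosage_from_calls

    rng = np.random.default_rng(config.seed if seed is None else seed)
    genmap = GeneticMap.uniform(config.n_chrom, config.chrom_length_cm)
    structure = simulate_structure(
        config.n_samples,
        n_sib_pairs=config.n_sib_pairs,
        household_size=config.household_size,
        households_per_block=config.households_per_block,
    )
    groups, props = simulate_proportions(config, rng)
    tracts = simulate_tracts(
        config, genmap, rng, proportions=props,
        sample_ids=structure.sample_ids, groups=groups,
    )
    regions = build_regions(genmap, config.n_regions)
    calls = tracts.rasterize(regions)
    dosages = dosage_from_calls(calls)
    if config.n_snvs > 0:
        snv_table = make_snv_table(genmap, config.n_snvs, config.snv_freqs, rng)
        genotypes = simulate_genotypes(tracts, snv_table, rng)
    else:
        snv_table = pd.DataFrame(
            columns=["snv_id", "chrom", "bp", "cM", "freq_AFR", "freq_EUR", "freq_NAM"]
        )
        genotypes = None
    covariates = simulate_covariates(config, groups, rng)
    covariates.index = pd.Index(
        [str(s) for s in structure.sample_ids], name="sample"
    )
    phenotypes = simulate_phenotypes(
        structure, covariates, config, rng, dosages=dosages, genotypes=genotypes
    )
    return SimulatedCohort(
        config=config, genmap=genmap, structure=structure, tracts=tracts,
        regions=regions, calls=calls, dosages=dosages, snv_table=snv_table,
        genotypes=genotypes, covariates=covariates, phenotypes=phenotypes,
    )
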