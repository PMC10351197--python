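"""Local-ancestry data model and I/O.

Local ancestry is stored per region x sample x haplotype with codes
0=AFR, 1=EUR, 2=NAM.  The on-disk dialect mirrors RFMix "msp" output:
a tab-separated table with columns

    chrom  start_bp  end_bp  start_cM  end_cM  <id>.0  <id>.1  ...

one row per local-ancestry region (half-open [start, end)), two columns
per sample (one per haplotype).  From the calls the package derives the
tested exposure — ancestry allelic dosages (0/1/2 copies of each
ancestry, summing to 2) — and global ancestry proportions as the
cM-length-weighted genome average of the local calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ANCESTRIES

__all__ = [
    "LocalAncestryCalls",
    "AncestryDosage",
    "read_local_ancestry",
    "write_local_ancestry",
    "dosage_from_calls",
    "global_from_local",
    "compute_pcs",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "write_vcf",
    "read_vcf",
]

REGION_COLS = ["chrom", "start_bp", "end_bp", "start_cM", "end_cM"]


@dataclass
class LocalAncestryCalls:
    """Per-haplotype ancestry over sorted, non-overlapping regions."""

    regions: pd.DataFrame  # region_id, chrom, start_bp, end_bp, start_cM, end_cM
    sample_ids: np.ndarray
    codes: np.ndarray  # (n_regions, n_samples, 2) int8 in {0,1,2}

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise ValueError("empty region list")
        self.sample_ids = np.asarray(self.sample_ids)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.regions), len(self.sample_ids), 2):
            raise ValueError("codes shape does not match regions x samples x 2")
        if self.codes.min() < 0 or self.codes.max() > 2:
            raise ValueError("ancestry codes must be in {0, 1, 2}")
        if "region_id" not in self.regions.columns:
            self.regions = self.regions.copy()
            self.regions.insert(0, "region_id", np.arange(len(self.regions)))
        for chrom, sub in self.regions.groupby("chrom", sort=False):
            s = sub["start_cM"].to_numpy()
            e = sub["end_cM"].to_numpy()
            if np.any(e[:-1] > s[1:] + 1e-9) or np.any(np.diff(s) < 0):
                raise ValueError(f"regions overlap or unsorted on chromosome {chrom}")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class AncestryDosage:
    """Ancestry allelic dosages: (n_regions, n_samples, 3), rows sum to 2."""

    regions: pd.DataFrame
    sample_ids: np.ndarray
    values: np.ndarray  # int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.all(self.values.sum(axis=2) == 2):
            raise ValueError("ancestry dosages must sum to 2 per sample per region")
        self._rid_to_row = {
            int(r): i for i, r in enumerate(self.regions["region_id"].to_numpy())
        }

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_index(self, region_id: int) -> int:
        return self._rid_to_row[int(region_id)]

    def region_dosage(self, region_id: int) -> np.ndarray:
        """(n_samples, 3) dosage matrix for one region."""
        return self.values[self.region_index(region_id)].astype(float)


def dosage_from_calls(calls: LocalAncestryCalls) -> AncestryDosage:
    """Count haplotype copies of each ancestry: d_A + d_E + d_N = 2."""
    vals = np.stack([(calls.codes == a).sum(axis=2) for a in range(3)], axis=2)
    return AncestryDosage(
        regions=calls.regions, sample_ids=calls.sample_ids,
        values=vals.astype(np.int8),
    )


def global_from_local(calls: LocalAncestryCalls) -> pd.DataFrame:
    """Global ancestry: cM-length-weighted genome average of local calls.

    Returns a DataFrame indexed by sample with columns p_AFR, p_EUR,
    p_NAM summing to 1 (each haplotype contributes weight 1/2).
    """
    w = (calls.regions["end_cM"] - calls.regions["start_cM"]).to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero total map length")
    props = np.zeros((calls.n_samples, 3))
    for a in range(3):
        ind = (calls.codes == a).sum(axis=2) / 2.0  # (n_regions, n_samples)
        props[:, a] = ind.T @ w
    props /= w.sum()
    return pd.DataFrame(
        props, index=[str(s) for s in calls.sample_ids],
        columns=[f"p_{a}" for a in ANCESTRIES],
    ).rename_axis("sample")


# ---------------------------------------------------------------------------
# local-ancestry TSV dialect
# ---------------------------------------------------------------------------


def write_local_ancestry(calls: LocalAncestryCalls, path) -> None:
    cols = {c: calls.regions[c].to_numpy() for c in REGION_COLS}
    for i, s in enumerate(calls.sample_ids):
        cols[f"{s}.0"] = calls.codes[:, i, 0]
        cols[f"{s}.1"] = calls.codes[:, i, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_local_ancestry(path) -> LocalAncestryCalls:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REGION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    hap_cols = [c for c in df.columns if c not in REGION_COLS]
    ids, haps = [], {}
    for c in hap_cols:
        base, dot, h = c.rpartition(".")
        if dot != "." or h not in ("0", "1"):
            raise ValueError(f"{path}: column {c!r} is not a <sample>.<hap> column")
        haps.setdefault(base, set()).add(h)
        if base not in ids:
            ids.append(base)
    bad = [s for s, hs in haps.items() if hs != {"0", "1"}]
    if bad:
        raise ValueError(f"{path}: samples without exactly 2 haplotypes: {bad}")
    codes = np.empty((len(df), len(ids), 2), dtype=np.int64)
    for i, s in enumerate(ids):
        codes[:, i, 0] = df[f"{s}.0"].to_numpy()
        codes[:, i, 1] = df[f"{s}.1"].to_numpy()
    bad_rows = np.flatnonzero((codes < 0).any(axis=(1, 2)) | (codes > 2).any(axis=(1, 2)))
    if len(bad_rows):
        raise ValueError(
            f"{path}: unknown ancestry code at line {int(bad_rows[0]) + 2}"
        )
    regions = df[REGION_COLS].copy()
    regions.insert(0, "region_id", np.arange(len(regions)))
    return LocalAncestryCalls(
        regions=regions, sample_ids=np.array(ids), codes=codes.astype(np.int8)
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotype_tsv(snv_table, genotypes, sample_ids, path) -> None:
    """SNV x sample allele-count table with SNV metadata columns."""
    geno_cols = pd.DataFrame(
        {str(s): genotypes[:, i] for i, s in enumerate(sample_ids)},
        index=snv_table.index,
    )
    out = pd.concat([snv_table[["snv_id", "chrom", "bp", "cM"]], geno_cols],
                    axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snv_id", "chrom", "bp", "cM"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    geno = df[sample_cols].to_numpy(dtype=np.int8)
    return df[meta_cols].copy(), geno, np.array(sample_cols)


def write_vcf(snv_table, genotypes, sample_ids, path) -> None:
    """Minimal unphased VCF v4.2 with GT only (REF=A, ALT=G placeholders)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in sample_ids) + "\n")
        for j, row in enumerate(snv_table.itertuples(index=False)):
            gts = "\t".join(gt_map[int(g)] for g in genotypes[j])
            fh.write(
                f"{row.chrom}\t{int(row.bp)}\t{row.snv_id}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read ALT-allele counts from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    rows, genos = [], []
    for var in vcf:
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS))
        gt = np.asarray(var.gt_types)  # 0=hom-ref,1=het,2=hom-alt(cyvcf2:3),3=unknown
        counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        genos.append(counts)
    table = pd.DataFrame(rows, columns=["snv_id", "chrom", "bp"])
    return table, np.asarray(genos, dtype=np.int8), ids


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


def compute_pcs(genotypes: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k genotype PCs for population-structure adjustment.

    SNVs are centered by mean and scaled by sqrt(2 p (1-p)); monomorphic
    SNVs are dropped.  Components are returned orthonormal (unit-norm
    columns, ordered by variance explained) with signs fixed so the
    first sample's coordinate is non-negative.  Returns (n_samples, k).
    """
    from sklearn.decomposition import PCA

    G = np.asarray(genotypes, dtype=float)  # (n_snvs, n_samples)
    p = G.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNVs monomorphic")
    G = G[poly]
    p = p[poly]
    if G.shape[1] < k + 1 or G.shape[0] < k:
        raise ValueError("not enough samples or SNVs for requested PCs")
    Z = (G - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    pcs = PCA(n_components=k, svd_solver="full").fit_transform(Z.T)
    pcs = pcs / np.linalg.norm(pcs, axis=0)
    sign = np.where(pcs[0] < 0, -1.0, 1.0)
    return pcs * sign
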