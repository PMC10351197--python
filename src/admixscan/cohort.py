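"""Cohort relatedness structure: kinship plus household / census-block labels.

These three objects define the three random effects of every mixed model
in the package: a genetic effect with covariance proportional to twice
the kinship matrix, and exchangeable household and census-block effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CohortStructure"]


@dataclass
class CohortStructure:
    """Sample ids, kinship matrix and household/block cluster labels.

    Kinship uses the standard coefficient convention: 0.5 on the diagonal
    for outbred individuals, 0.25 for full sibs, 0 for unrelated pairs.
    ``kinship`` may be dense or scipy-sparse; it is stored as CSR.
    Households must nest within census blocks.
    """

    sample_ids: np.ndarray
    kinship: sp.csr_matrix
    household: np.ndarray
    block: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        n = len(self.sample_ids)
        if len(np.unique(self.sample_ids)) != n:
            raise ValueError("sample ids not unique")
        K = self.kinship
        if not sp.issparse(K):
            K = sp.csr_matrix(np.asarray(K, dtype=float))
        K = K.tocsr().astype(float)
        if K.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if abs(K - K.T).max() > 1e-10:
            raise ValueError("kinship not symmetric")
        self.kinship = K
        self.household = np.asarray(self.household)
        self.block = np.asarray(self.block)
        if len(self.household) != n or len(self.block) != n:
            raise ValueError("cluster label length mismatch")
        # households nest within blocks
        hh = pd.DataFrame({"h": self.household, "b": self.block})
        if (hh.groupby("h")["b"].nunique() > 1).any():
            raise ValueError("households must nest within census blocks")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cluster_indicator(self, labels: np.ndarray) -> sp.csr_matrix:
        """Sparse n x n_clusters 0/1 design matrix for a label vector."""
        codes, _ = pd.factorize(labels)
        n = len(labels)
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, codes.max() + 1)
        )

    # -- I/O -----------------------------------------------------------

    def write(self, kinship_path, clusters_path) -> None:
        ids = [str(s) for s in self.sample_ids]
        pd.DataFrame(self.kinship.toarray(), index=ids, columns=ids).to_csv(
            kinship_path, sep="\t"
        )
        pd.DataFrame(
            {"sample": ids, "household": self.household, "block": self.block}
        ).to_csv(clusters_path, sep="\t", index=False)

    @classmethod
    def read(cls, kinship_path, clusters_path) -> "CohortStructure":
        kin = pd.read_csv(kinship_path, sep="\t", index_col=0)
        clusters = pd.read_csv(clusters_path, sep="\t", dtype=str)
        ids = kin.index.astype(str).to_numpy()
        clusters = clusters.set_index("sample").loc[ids]
        return cls(
            sample_ids=ids,
            kinship=sp.csr_matrix(kin.to_numpy(dtype=float)),
            household=clusters["household"].to_numpy(),
            block=clusters["block"].to_numpy(),
        )
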