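"""Genetic maps: the bp <-> centiMorgan coordinate system.

All distance arithmetic in the package (tract lengths, the 10-cM
conditioning window, region widths) is done in centiMorgans; physical
bp coordinates exist for interoperability with VCF and known-hit files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "build_regions"]


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map over one or more chromosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``chrom`` (str), ``bp`` (1-based int, strictly increasing
        within chromosome) and ``cM`` (non-decreasing within chromosome).
        At least two points per chromosome.
    """

    table: pd.DataFrame
    _by_chrom: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "bp", "cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if len(self.table) == 0:
            raise ValueError("empty genetic map")
        self.table = self.table.copy()
        self.table["chrom"] = self.table["chrom"].astype(str)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy(dtype=np.int64)
            cm = sub["cM"].to_numpy(dtype=float)
            if len(bp) < 2:
                raise ValueError(f"chromosome {chrom}: need >= 2 map points")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"chromosome {chrom}: bp not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM decreasing")
            if np.any(cm < 0):
                raise ValueError(f"chromosome {chrom}: negative cM")
            self._by_chrom[chrom] = (bp, cm)

    # -- construction -------------------------------------------------

    @classmethod
    def uniform(
        cls, n_chrom: int = 1, length_cm: float = 100.0, cm_per_mb: float = 1.0
    ) -> "GeneticMap":
        """Constant-rate map: ``length_cm`` per chromosome at ``cm_per_mb``."""
        rows = []
        length_bp = int(round(length_cm / cm_per_mb * 1e6))
        for i in range(n_chrom):
            chrom = str(i + 1)
            rows.append((chrom, 1, 0.0))
            rows.append((chrom, length_bp, length_cm))
        return cls(pd.DataFrame(rows, columns=["chrom", "bp", "cM"]))

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    # -- queries ------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def length_cm(self, chrom: str) -> float:
        bp, cm = self._by_chrom[str(chrom)]
        return float(cm[-1] - cm[0])

    @property
    def total_morgans(self) -> float:
        return sum(self.length_cm(c) for c in self.chromosomes) / 100.0

    def cm_span(self, chrom: str) -> tuple[float, float]:
        bp, cm = self._by_chrom[str(chrom)]
        return float(cm[0]), float(cm[-1])

    def bp_span(self, chrom: str) -> tuple[int, int]:
        bp, cm = self._by_chrom[str(chrom)]
        return int(bp[0]), int(bp[-1])

    def cm_at(self, chrom: str, bp_pos) -> np.ndarray:
        """Interpolated cM position(s); error if outside the map span."""
        bp, cm = self._by_chrom[str(chrom)]
        pos = np.asarray(bp_pos, dtype=float)
        if np.any(pos < bp[0]) or np.any(pos > bp[-1]):
            raise ValueError(f"position outside map span of chromosome {chrom}")
        return np.interp(pos, bp, cm)

    def bp_at(self, chrom: str, cm_pos) -> np.ndarray:
        """Inverse interpolation cM -> bp (rounded to integer positions)."""
        bp, cm = self._by_chrom[str(chrom)]
        pos = np.asarray(cm_pos, dtype=float)
        if np.any(pos < cm[0]) or np.any(pos > cm[-1]):
            raise ValueError(f"cM position outside map span of chromosome {chrom}")
        return np.rint(np.interp(pos, cm, bp)).astype(np.int64)


def build_regions(genmap: GeneticMap, n_regions: int) -> pd.DataFrame:
    """Tile the map with ``n_regions`` equal-cM local-ancestry regions.

    Regions are allocated to chromosomes proportionally to cM length
    (at least one per chromosome) and are half-open ``[start, end)`` in
    cM.  Returns a DataFrame with columns
    ``region_id, chrom, start_bp, end_bp, start_cM, end_cM``.
    """
    if n_regions < len(genmap.chromosomes):
        raise ValueError("need at least one region per chromosome")
    lengths = np.array([genmap.length_cm(c) for c in genmap.chromosomes])
    alloc = np.maximum(1, np.rint(n_regions * lengths / lengths.sum()).astype(int))
    # fix rounding so totals match exactly
    while alloc.sum() > n_regions:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_regions:
        alloc[np.argmax(lengths / alloc)] += 1
    rows = []
    rid = 0
    for chrom, k in zip(genmap.chromosomes, alloc):
        lo, hi = genmap.cm_span(chrom)
        edges = np.linspace(lo, hi, k + 1)
        bp_edges = genmap.bp_at(chrom, edges)
        for i in range(k):
            rows.append(
                (rid, chrom, int(bp_edges[i]), int(bp_edges[i + 1]),
                 float(edges[i]), float(edges[i + 1]))
            )
            rid += 1
    return pd.DataFrame(
        rows, columns=["region_id", "chrom", "start_bp", "end_bp", "start_cM", "end_cM"]
    )
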