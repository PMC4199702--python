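"""Genetic-map assembly from adjacent-pair recombination-fraction estimates.

Marker order within a chromosome comes from physical position (no de novo
ordering); cM coordinates accumulate Haldane distances between adjacent pairs,
anchored at 0 for the first marker of each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rf import HetModel, adjacent_rf_scan
from .matrix import GenotypeMatrix

__all__ = ["GeneticMap", "build_map", "map_from_matrix", "compare_maps", "summary_table"]

# r_hat this close to the search bracket's upper end means "no linkage detected";
# the Haldane distance would be effectively unbounded.
_UNLINKED_R = 0.5 - 2e-6

#: cM per recombination event per meiosis, the usual reporting convention
#: (50 cM == 1 recombination per meiosis).
CM_PER_RECOMBINATION = 50.0


@dataclass
class GeneticMap:
    """Per-chromosome marker cM positions.

    ``table`` has one row per marker: marker (index), chrom, pos (bp), cm.
    """

    table: pd.DataFrame

    def chromosome_lengths(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=float, name="length_cm")
        g = self.table.groupby("chrom", sort=False)["cm"].max()
        return g.rename("length_cm")

    def total_length(self) -> float:
        return float(self.chromosome_lengths().sum())

    def marker_cm(self) -> pd.Series:
        return self.table["cm"]

    def write_tsv(self, path) -> None:
        self.table.rename_axis("marker").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t", index_col="marker", dtype={"chrom": str})
        return cls(t[["chrom", "pos", "cm"]])


def build_map(scan: pd.DataFrame) -> GeneticMap:
    """Assemble a map from an :func:`exhet.rf.adjacent_rf_scan` result.

    Positions are cumulative Haldane distances, first marker of each
    chromosome at 0 cM.  Pairs estimated at the ``r = 0.5`` search boundary
    have no finite map distance; they (and pairs with no informative data)
    raise, naming the offending pairs, rather than silently distorting totals.
    """
    if scan.empty:
        return GeneticMap(
            pd.DataFrame({"chrom": [], "pos": [], "cm": []}, index=pd.Index([], name="marker"))
        )
    bad = scan[scan["r_hat"].isna() | (scan["r_hat"] >= _UNLINKED_R)]
    if len(bad):
        pairs = ", ".join(f"{a}~{b}" for a, b in zip(bad["marker_a"], bad["marker_b"]))
        raise ValueError(f"unlinked or uninformative adjacent pairs (r_hat at boundary or NaN): {pairs}")
    records = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        cm = np.concatenate([[0.0], np.cumsum(grp["cm"].to_numpy())])
        markers = [grp["marker_a"].iloc[0], *grp["marker_b"]]
        pos = [grp["pos_a"].iloc[0], *grp["pos_b"]]
        for mk, p, c in zip(markers, pos, cm):
            records.append((mk, chrom, p, c))
    t = pd.DataFrame(records, columns=["marker", "chrom", "pos", "cm"]).set_index("marker")
    return GeneticMap(t)


def map_from_matrix(matrix: GenotypeMatrix, m: HetModel, tol: float = 1e-6) -> GeneticMap:
    """Convenience: adjacent-pair scan followed by map assembly."""
    return build_map(adjacent_rf_scan(matrix, m, tol=tol))


def compare_maps(map_a: GeneticMap, map_b: GeneticMap) -> pd.DataFrame:
    """Per-chromosome and total differences between two maps of the same markers.

    Returns, per chromosome plus a "total" row: lengths under both maps,
    ``delta_cm = length_a - length_b``, ``delta_pct = 100 * delta_cm / length_a``
    and ``delta_recombinations = delta_cm / 50`` (the 50 cM per recombination
    per meiosis reporting convention).
    """
    if list(map_a.table.index) != list(map_b.table.index):
        raise ValueError("maps are over different marker sets or orders")
    la = map_a.chromosome_lengths()
    lb = map_b.chromosome_lengths()
    out = pd.DataFrame({"length_a": la, "length_b": lb})
    out.loc["total"] = [la.sum(), lb.sum()]
    out["delta_cm"] = out["length_a"] - out["length_b"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["delta_pct"] = 100.0 * out["delta_cm"] / out["length_a"]
    out["delta_recombinations"] = out["delta_cm"] / CM_PER_RECOMBINATION
    return out


def summary_table(maps: dict[str, GeneticMap]) -> pd.DataFrame:
    """Chromosome-by-method table of map lengths (one column per method)."""
    cols = {}
    for name, gm in maps.items():
        lengths = gm.chromosome_lengths()
        lengths.loc["total"] = lengths.sum()
        cols[name] = lengths
    return pd.DataFrame(cols)
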