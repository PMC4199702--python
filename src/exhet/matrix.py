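"""Genotype-matrix container for biparental selfed populations.

Genotypes are stored as an ``int8`` array with codes 0 (A, homozygous for the
parent-1 allele), 1 (H, heterozygous), 2 (B, homozygous for the parent-2
allele) and -1 (missing).  Markers carry a chromosome label and a 1-based
physical position and are kept sorted by position within each chromosome;
chromosomes stay in their order of first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MISSING", "CODES", "SYMBOLS", "GenotypeMatrix"]

MISSING: int = -1
CODES = {"A": 0, "H": 1, "B": 2, "-": MISSING}
SYMBOLS = {0: "A", 1: "H", 2: "B", MISSING: "-"}


@dataclass(eq=False)
class GenotypeMatrix:
    """Individuals x ordered markers with genotype codes {A, H, B, missing}.

    Parameters
    ----------
    individuals
        Individual identifiers, one per row of ``geno``.
    markers
        DataFrame indexed by unique marker identifier with columns ``chrom``
        (str) and ``pos`` (int, 1-based physical bp).
    geno
        ``(n_individuals, n_markers)`` int8 array of genotype codes.
    """

    individuals: list[str]
    markers: pd.DataFrame
    geno: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.individuals = [str(i) for i in self.individuals]
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("geno must be 2-D (individuals x markers)")
        if self.geno.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.geno, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if not {"chrom", "pos"} <= set(self.markers.columns):
            raise ValueError("markers must have 'chrom' and 'pos' columns")
        if self.markers.index.has_duplicates:
            dup = self.markers.index[self.markers.index.duplicated()][0]
            raise ValueError(f"duplicate marker identifier: {dup!r}")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        for chrom, pos in self._by_chrom():
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"markers on chromosome {chrom!r} are not position-sorted")

    def _by_chrom(self):
        chroms = self.markers["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            yield chrom, self.markers["pos"].to_numpy()[chroms == chrom]

    # -- basic queries ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.markers["chrom"].to_numpy()))

    def chrom_slices(self) -> dict:
        """Column index array per chromosome, in marker order."""
        chroms = self.markers["chrom"].to_numpy()
        return {c: np.flatnonzero(chroms == c) for c in self.chromosomes}

    def marker_missingness(self) -> np.ndarray:
        return (self.geno == MISSING).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return (self.geno == MISSING).mean(axis=1)

    # -- subsetting -------------------------------------------------------

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.individuals[i] for i in index],
            self.markers.copy(),
            self.geno[index],
        )

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            list(self.individuals),
            self.markers.iloc[index].copy(),
            self.geno[:, index],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individuals), self.markers.copy(), self.geno.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individuals == other.individuals
            and self.markers.equals(other.markers)
            and np.array_equal(self.geno, other.geno)
        )
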