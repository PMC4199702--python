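"""Reading and writing genotype matrices.

The delimited-text dialect follows the common cross-file layout for inbred
populations: a header row of the individual-id column name followed by marker
names, a second row with the chromosome of each marker, a third row with its
physical position, then one row per individual with genotype symbols
A / H / B / ``-`` (missing; empty cells and ``NA`` are accepted on input).

VCF import recodes a biparental population against two named parent samples.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import CODES, MISSING, SYMBOLS, GenotypeMatrix

__all__ = ["read_genotype_csv", "write_genotype_csv", "import_vcf"]

_MISSING_INPUT = {"-", "", "NA", "N"}


def read_genotype_csv(path) -> GenotypeMatrix:
    """Parse a genotype-matrix CSV; malformed content raises with row/column context."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
            chrom_row = next(reader)
            pos_row = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: file must start with marker/chrom/pos header rows") from None
    if len(header) < 2:
        raise ValueError(f"{path}: header has no marker columns")
    names = header[1:]
    if len(set(names)) != len(names):
        dup = next(n for i, n in enumerate(names) if n in names[:i])
        raise ValueError(f"{path}: duplicate marker name {dup!r}")
    if len(chrom_row) != len(header) or len(pos_row) != len(header):
        raise ValueError(f"{path}: chrom/pos rows do not match header width")
    try:
        pos = [int(p) for p in pos_row[1:]]
    except ValueError as e:
        raise ValueError(f"{path}: non-integer physical position ({e})") from None
    markers = pd.DataFrame(
        {"chrom": [str(c) for c in chrom_row[1:]], "pos": pos},
        index=pd.Index(names, name="marker"),
    )
    individuals: list[str] = []
    rows: list[list[int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for _ in range(3):
            next(reader)
        for lineno, row in enumerate(reader, start=4):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            individuals.append(row[0])
            codes = []
            for col, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell in _MISSING_INPUT:
                    codes.append(MISSING)
                elif cell in CODES:
                    codes.append(CODES[cell])
                else:
                    raise ValueError(
                        f"{path}:{lineno}: column {col} (marker {names[col - 2]!r}): "
                        f"unknown genotype symbol {cell!r}"
                    )
            rows.append(codes)
    geno = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(names)), dtype=np.int8)
    )
    try:
        return GenotypeMatrix(individuals, markers, geno)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_genotype_csv(matrix: GenotypeMatrix, path) -> None:
    """Write the canonical formatting; round-trips byte-stably through the reader."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", *matrix.markers.index])
        writer.writerow(["", *matrix.markers["chrom"]])
        writer.writerow(["", *(str(int(p)) for p in matrix.markers["pos"])])
        for ind, row in zip(matrix.individuals, matrix.geno):
            writer.writerow([ind, *(SYMBOLS[int(g)] for g in row)])


def import_vcf(
    path,
    parent1_sample: str,
    parent2_sample: str,
    min_gq: int = 20,
    min_typed_fraction: float = 0.25,
) -> GenotypeMatrix:
    """Build a genotype matrix from a VCF of a biparental population.

    Retains biallelic sites at which the two parents are homozygous for
    different alleles (any heterozygous or missing parent call drops the
    site).  Offspring genotypes are recoded by parental origin: homozygous for
    the parent-1 allele -> A, heterozygous -> H, homozygous for the parent-2
    allele -> B.  Genotypes (parents included) with GQ below ``min_gq`` are
    masked to missing before any site-level decision; sites typed in fewer
    than ``min_typed_fraction`` of all samples after masking are dropped.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    for parent in (parent1_sample, parent2_sample):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not in VCF ({len(samples)} samples)")
    i1 = samples.index(parent1_sample)
    i2 = samples.index(parent2_sample)
    offspring_idx = [i for i in range(len(samples)) if i not in (i1, i2)]
    offspring = [samples[i] for i in offspring_idx]

    names, chroms, positions, rows = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1 or variant.ALT[0].startswith("<"):
            continue
        gq = variant.gt_quals
        if gq is None or (np.asarray(gq) < 0).all():
            raise ValueError(f"{variant.CHROM}:{variant.POS}: VCF has no GQ field")
        # allele dosage per sample: 0, 1, 2 alt copies; 3 == unknown in cyvcf2
        types = variant.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        typed = (types != 2) & (np.asarray(gq) >= min_gq)
        if typed.mean() < min_typed_fraction:
            continue
        if not (typed[i1] and typed[i2]):
            continue
        p1, p2 = types[i1], types[i2]
        if {p1, p2} != {0, 3}:
            continue  # parents must be opposite homozygotes
        # map HOM for parent-1's allele -> A(0), HET -> H(1), other HOM -> B(2)
        recode = {p1: 0, 1: 1, p2: 2}
        geno_row = np.full(len(offspring_idx), MISSING, dtype=np.int8)
        for out_col, sample_i in enumerate(offspring_idx):
            if typed[sample_i]:
                geno_row[out_col] = recode[types[sample_i]]
        name = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        names.append(name)
        chroms.append(str(variant.CHROM))
        positions.append(int(variant.POS))
        rows.append(geno_row)

    markers = pd.DataFrame(
        {"chrom": chroms, "pos": positions}, index=pd.Index(names, name="marker")
    )
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(offspring), 0), dtype=np.int8)
    )
    # enforce within-chromosome position order (VCFs are usually sorted already)
    if len(markers):
        order = np.lexsort((markers["pos"].to_numpy(), pd.factorize(markers["chrom"])[0]))
        markers = markers.iloc[order]
        geno = geno[:, order]
    return GenotypeMatrix(offspring, markers, geno)
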