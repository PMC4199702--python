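"""Genotype quality control for RIL populations with excess heterozygosity.

The procedure mirrors iterative map-construction practice: remove markers and
individuals with high missingness, collapse duplicated individuals, drop
physically redundant markers, flag individuals with aberrant genotype
proportions, test markers for segregation distortion against the population's
*observed* heterozygosity (not the Mendelian expectation), mask tight double
recombinations, and re-estimate the population heterozygosity H between
passes.  Testing distortion against the observed H matters: under excess
heterozygosity a Mendelian null wrongly rejects well-behaved markers in bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix
from .mapping import GeneticMap

__all__ = [
    "MarkerSegregation",
    "QcReport",
    "estimate_H",
    "distortion_test",
    "marker_segregation",
    "filter_markers_by_distortion",
    "iterative_distortion_filter",
    "filter_missingness",
    "drop_duplicate_individuals",
    "drop_redundant_markers",
    "mask_tight_double_recombinants",
    "flag_outlier_individuals",
    "qc_pipeline",
]


@dataclass(frozen=True)
class MarkerSegregation:
    """Genotype counts at one marker and its distortion-test p-value."""

    n_a: int
    n_h: int
    n_b: int
    p_value: float


@dataclass
class QcReport:
    """Audit trail of a QC step: what was removed or masked, and why."""

    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)
    flagged_individuals: list[tuple[str, str]] = field(default_factory=list)
    masked_genotype_count: int = 0
    H_before: float | None = None
    H_after: float | None = None

    def merge(self, other: "QcReport") -> "QcReport":
        return QcReport(
            removed_individuals=self.removed_individuals + other.removed_individuals,
            removed_markers=self.removed_markers + other.removed_markers,
            flagged_individuals=self.flagged_individuals + other.flagged_individuals,
            masked_genotype_count=self.masked_genotype_count + other.masked_genotype_count,
            H_before=self.H_before if self.H_before is not None else other.H_before,
            H_after=other.H_after if other.H_after is not None else self.H_after,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("individual", i, reason) for i, reason in self.removed_individuals]
            + [("marker", m, reason) for m, reason in self.removed_markers]
            + [("flagged_individual", i, reason) for i, reason in self.flagged_individuals]
        )
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def estimate_H(matrix: GenotypeMatrix, per_chromosome: bool = False):
    """Proportion heterozygous among non-missing genotypes.

    With ``per_chromosome=True`` returns a Series of one H per chromosome
    (linkage group), enabling group-specific retention parameters.
    """
    if per_chromosome:
        out = {}
        for chrom, cols in matrix.chrom_slices().items():
            sub = matrix.geno[:, cols]
            typed = int((sub != MISSING).sum())
            if typed == 0:
                raise ValueError(f"chromosome {chrom!r} has no non-missing genotypes")
            out[chrom] = float((sub == 1).sum() / typed)
        return pd.Series(out, name="H")
    typed = int((matrix.geno != MISSING).sum())
    if typed == 0:
        raise ValueError("matrix has no non-missing genotypes")
    return float((matrix.geno == 1).sum() / typed)


def _distortion_stats(counts: np.ndarray, H_null: float):
    """Chi-square statistic and log-scale p-value, vectorised over markers.

    counts: (..., 3) array of (n_A, n_H, n_B).  Expected proportions are
    ((1-H)/2, H, (1-H)/2).  The survival function is evaluated on the log
    scale so thresholds far below the double-precision underflow limit
    (e.g. 1e-300) still compare meaningfully.
    """
    if not 0.0 < H_null < 1.0:
        raise ValueError(f"H_null must lie in (0, 1), got {H_null}")
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("distortion test needs at least one typed genotype")
    exp_prop = np.array([(1.0 - H_null) / 2.0, H_null, (1.0 - H_null) / 2.0])
    expected = total[..., None] * exp_prop
    chi2 = ((counts - expected) ** 2 / expected).sum(axis=-1)
    logp = stats.chi2.logsf(chi2, df=2)
    return chi2, logp


def distortion_test(n_a: int, n_h: int, n_b: int, H_null: float) -> float:
    """Chi-square (df=2) goodness-of-fit p-value against the distortion null.

    The null segregation is (1-H)/2 : H : (1-H)/2; ``H_null = 0.5`` gives the
    textbook Mendelian 1:2:1 test.
    """
    _, logp = _distortion_stats(np.array([n_a, n_h, n_b]), H_null)
    return float(np.exp(logp))


def marker_segregation(matrix: GenotypeMatrix, H_null: float) -> pd.DataFrame:
    """Per-marker genotype counts, chi-square statistic, p-value and log10 p."""
    counts = np.stack(
        [(matrix.geno == g).sum(axis=0) for g in (0, 1, 2)], axis=-1
    )
    typed = counts.sum(axis=-1)
    chi2 = np.full(len(typed), np.nan)
    logp = np.full(len(typed), np.nan)
    ok = typed > 0
    if ok.any():
        chi2[ok], logp[ok] = _distortion_stats(counts[ok], H_null)
    return pd.DataFrame(
        {
            "chrom": matrix.markers["chrom"].to_numpy(),
            "n_a": counts[:, 0],
            "n_h": counts[:, 1],
            "n_b": counts[:, 2],
            "chi2": chi2,
            "p_value": np.exp(logp),
            "log10_p": logp / np.log(10.0),
        },
        index=matrix.markers.index,
    )


def filter_markers_by_distortion(
    matrix: GenotypeMatrix,
    H_null: float,
    alpha: float = 1e-15,
    per_chromosome_alpha: dict[str, float] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove markers whose segregation deviates from the H_null ratio at p < alpha.

    ``per_chromosome_alpha`` overrides the threshold on named chromosomes
    (e.g. relaxing it where a known selected locus distorts a whole region).
    Comparison is done on the log scale; ``alpha = 0`` removes nothing.
    Markers with no typed genotypes are not judged here (missingness filters
    handle them).
    """
    seg = marker_segregation(matrix, H_null)
    log_alpha = np.full(len(seg), -np.inf if alpha == 0.0 else np.log(alpha))
    for chrom, a in (per_chromosome_alpha or {}).items():
        log_alpha[seg["chrom"].to_numpy() == chrom] = -np.inf if a == 0.0 else np.log(a)
    logp = seg["log10_p"].to_numpy() * np.log(10.0)
    drop = np.where(np.isnan(logp), False, logp < log_alpha)
    report = QcReport(
        removed_markers=[
            (mk, f"distortion p={p:.3g}")
            for mk, p in zip(seg.index[drop], seg["p_value"].to_numpy()[drop])
        ]
    )
    return matrix.take_markers(~drop), report


def iterative_distortion_filter(
    matrix: GenotypeMatrix,
    alpha: float = 1e-15,
    per_chromosome_alpha: dict[str, float] | None = None,
    max_rounds: int = 10,
) -> tuple[GenotypeMatrix, QcReport, list[float]]:
    """Distortion filtering with iterative re-estimation of H.

    Each round estimates H on the currently retained markers and re-applies
    the distortion test to the *original* marker set with the updated null, so
    a marker wrongly removed under an early H can re-enter.  Stops when the
    retained set is stable (typically two passes) or after ``max_rounds``.
    Returns the filtered matrix, a report, and the history of H values.
    """
    H_history = [estimate_H(matrix)]
    current = matrix
    for _ in range(max_rounds):
        filtered, report = filter_markers_by_distortion(
            matrix, H_history[-1], alpha=alpha, per_chromosome_alpha=per_chromosome_alpha
        )
        H_history.append(estimate_H(filtered))
        if set(filtered.markers.index) == set(current.markers.index):
            current = filtered
            break
        current = filtered
    report = QcReport(
        removed_markers=report.removed_markers,
        H_before=H_history[0],
        H_after=H_history[-1],
    )
    return current, report, H_history


def filter_missingness(
    matrix: GenotypeMatrix,
    max_marker_missing: float = 0.60,
    max_individual_missing: float = 0.60,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers, then individuals, with missingness at or above threshold."""
    for thr in (max_marker_missing, max_individual_missing):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("missingness thresholds must lie in [0, 1]")
    mm = matrix.marker_missingness()
    drop_m = mm >= max_marker_missing
    report = QcReport(
        removed_markers=[
            (mk, f"missingness {frac:.2f}")
            for mk, frac in zip(matrix.markers.index[drop_m], mm[drop_m])
        ]
    )
    out = matrix.take_markers(~drop_m)
    im = out.individual_missingness()
    drop_i = im >= max_individual_missing
    report.removed_individuals = [
        (out.individuals[i], f"missingness {im[i]:.2f}") for i in np.flatnonzero(drop_i)
    ]
    return out.take_individuals(~drop_i), report


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def drop_duplicate_individuals(
    matrix: GenotypeMatrix, min_share: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Collapse groups of individuals sharing >= ``min_share`` of genotypes.

    Concordance is computed over mutually non-missing markers.  Pairs at or
    above the threshold are linked; each connected component keeps its member
    with the least missingness (ties broken by input order) and drops the
    rest.  Pairs with no mutual non-missing markers are treated as distinct.
    """
    n = matrix.n_individuals
    G = matrix.geno
    typed = G != MISSING
    uf = _UnionFind(n)
    for i in range(n - 1):
        both = typed[i] & typed[i + 1 :]
        overlap = both.sum(axis=1)
        same = ((G[i] == G[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(overlap > 0, same / np.maximum(overlap, 1), 0.0)
        for j in np.flatnonzero(share >= min_share):
            uf.union(i, i + 1 + j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    missing_frac = matrix.individual_missingness()
    drop = np.zeros(n, dtype=bool)
    removed = []
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda i: (missing_frac[i], i))
        for i in members:
            if i != keep:
                drop[i] = True
                removed.append(
                    (matrix.individuals[i], f"duplicate_of:{matrix.individuals[keep]}")
                )
    return matrix.take_individuals(~drop), QcReport(removed_individuals=removed)


def drop_redundant_markers(
    matrix: GenotypeMatrix, window_bp: int = 2000
) -> tuple[GenotypeMatrix, QcReport]:
    """Collapse runs of physically close markers with identical genotype vectors.

    Consecutive markers within ``window_bp`` of each other whose genotype
    vectors agree at every mutually non-missing individual are grouped; each
    group keeps its least-missing member.  This is the pragmatic reading of
    removing markers "uninformative due to close proximity".
    """
    names = matrix.markers.index.to_numpy()
    pos = matrix.markers["pos"].to_numpy()
    typed = matrix.geno != MISSING
    mm = matrix.marker_missingness()
    uf = _UnionFind(matrix.n_markers)
    for _, cols in matrix.chrom_slices().items():
        for j, k in zip(cols[:-1], cols[1:]):
            if pos[k] - pos[j] > window_bp:
                continue
            both = typed[:, j] & typed[:, k]
            if np.all(matrix.geno[both, j] == matrix.geno[both, k]):
                uf.union(j, k)
    groups: dict[int, list[int]] = {}
    for j in range(matrix.n_markers):
        groups.setdefault(uf.find(j), []).append(j)
    drop = np.zeros(matrix.n_markers, dtype=bool)
    removed = []
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda j: (mm[j], j))
        for j in members:
            if j != keep:
                drop[j] = True
                removed.append((names[j], f"redundant_with:{names[keep]}"))
    return matrix.take_markers(~drop), QcReport(removed_markers=removed)


def _mask_chromosome_once(geno_row, pos, window) -> list[int]:
    """Indices (into the chromosome's columns) of one masking pass for one individual."""
    obs = np.flatnonzero(geno_row != MISSING)
    if obs.size < 3:
        return []
    g = geno_row[obs]
    # run-length encode the non-missing subsequence
    boundaries = np.flatnonzero(np.diff(g) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [g.size]])
    to_mask: list[int] = []
    for run in range(1, len(starts) - 1):
        left_flank = obs[ends[run - 1] - 1]
        right_flank = obs[starts[run + 1]]
        if geno_row[left_flank] != geno_row[right_flank]:
            continue
        if pos[right_flank] - pos[left_flank] <= window:
            to_mask.extend(obs[starts[run] : ends[run]])
    return to_mask


def mask_tight_double_recombinants(
    matrix: GenotypeMatrix,
    window: float,
    units: str = "bp",
    genetic_map: GeneticMap | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Set genotypes inside tight double recombinations to missing.

    A tight double recombination is a run of one or more identical calls whose
    nearest non-missing flanks on both sides agree with each other, differ
    from the run, and lie within ``window`` of each other (flank-to-flank
    distance, in bp or in cM positions taken from ``genetic_map``).  Only the
    interior run is masked; chromosome ends are never masked.  Missing calls
    are transparent.  Masking repeats until stable, because removing a run can
    fuse its flanking runs into a new tight double recombinant; a non-missing
    call is only ever changed to missing, never to another genotype.
    """
    if units not in ("bp", "cM"):
        raise ValueError("units must be 'bp' or 'cM'")
    if units == "cM":
        if genetic_map is None:
            raise ValueError("cM-based masking requires a genetic map")
        cm = genetic_map.table["cm"]
        try:
            pos_all = cm.loc[matrix.markers.index].to_numpy()
        except KeyError as e:
            raise ValueError(f"genetic map is missing markers: {e}") from None
    else:
        pos_all = matrix.markers["pos"].to_numpy(dtype=float)
    out = matrix.copy()
    masked = 0
    for _, cols in matrix.chrom_slices().items():
        pos = pos_all[cols]
        for i in range(out.n_individuals):
            row = out.geno[i, cols]
            while True:
                idx = _mask_chromosome_once(row, pos, window)
                if not idx:
                    break
                row[idx] = MISSING
                masked += len(idx)
            out.geno[i, cols] = row
    return out, QcReport(masked_genotype_count=masked)


def flag_outlier_individuals(
    matrix: GenotypeMatrix, k: float = 3.0, remove: bool = False
) -> tuple[GenotypeMatrix, QcReport]:
    """Flag individuals whose genotype proportions fall outside Tukey fences.

    Computes per-individual fractions of A, H and B among non-missing calls
    and flags anyone outside ``[Q1 - k*IQR, Q3 + k*IQR]`` on any of the three.
    Removal is opt-in (``remove=True``); by default flagged individuals are
    only reported.  ``k = inf`` flags nothing.
    """
    typed = (matrix.geno != MISSING).sum(axis=1)
    if np.any(typed == 0):
        raise ValueError("individual with no non-missing genotypes; filter missingness first")
    fracs = np.stack(
        [(matrix.geno == g).sum(axis=1) / typed for g in (0, 1, 2)], axis=1
    )
    flagged = np.zeros(matrix.n_individuals, dtype=bool)
    if np.isfinite(k):
        q1, q3 = np.percentile(fracs, [25, 75], axis=0)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        flagged = ((fracs < lo) | (fracs > hi)).any(axis=1)
    labels = ["A", "H", "B"]
    details = [
        (
            matrix.individuals[i],
            "genotype proportions "
            + ",".join(f"{l}={f:.3f}" for l, f in zip(labels, fracs[i])),
        )
        for i in np.flatnonzero(flagged)
    ]
    if remove:
        return matrix.take_individuals(~flagged), QcReport(removed_individuals=details)
    return matrix.copy(), QcReport(flagged_individuals=details)


def qc_pipeline(
    matrix: GenotypeMatrix,
    max_marker_missing: float = 0.60,
    max_individual_missing: float = 0.60,
    duplicate_share: float = 0.90,
    redundant_window_bp: int | None = 2000,
    outlier_k: float = 3.0,
    remove_outliers: bool = False,
    distortion_alpha: float = 1e-15,
    per_chromosome_alpha: dict[str, float] | None = None,
    mask_window_bp: float | None = 2000.0,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC pass in the standard order.

    missingness -> duplicates -> redundant markers -> double-recombination
    masking (bp scale) -> outlier individuals -> iterative distortion filter
    with H re-estimation.  Any stage can be disabled by passing ``None`` (for
    windows) or extreme thresholds.
    """
    H0 = estimate_H(matrix)
    out, report = filter_missingness(matrix, max_marker_missing, max_individual_missing)
    out, rep = drop_duplicate_individuals(out, duplicate_share)
    report = report.merge(rep)
    if redundant_window_bp is not None:
        out, rep = drop_redundant_markers(out, redundant_window_bp)
        report = report.merge(rep)
    if mask_window_bp is not None:
        out, rep = mask_tight_double_recombinants(out, mask_window_bp, units="bp")
        report = report.merge(rep)
    out, rep = flag_outlier_individuals(out, k=outlier_k, remove=remove_outliers)
    report = report.merge(rep)
    out, rep, _ = iterative_distortion_filter(
        out, alpha=distortion_alpha, per_chromosome_alpha=per_chromosome_alpha
    )
    report = report.merge(rep)
    report.H_before = H0
    report.H_after = estimate_H(out)
    return out, report
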