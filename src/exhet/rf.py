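"""Recombination-fraction estimation under the excess-heterozygosity model.

For one marker pair the data reduce to a 3x3 table of genotype-pair counts
(AA/Aa/aa x BB/Bb/bb, missing dropped pairwise).  The likelihood is the
multinomial over the expected pair table from :func:`exhet.model.joint_genotype_table`
at the population's ``(h, t)``; the maximum over ``r`` in [0, 0.5] is located
with a golden-section search.  Map distances use the Haldane function
``d = -50 ln(1 - 2r)`` cM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "HetModel",
    "PairCounts",
    "RfEstimate",
    "pair_counts",
    "pair_loglik",
    "profile_loglik",
    "estimate_rf",
    "haldane_cm",
    "haldane_r",
    "adjacent_rf_scan",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_R_LO = 1e-6
_R_HI = 0.5 - 1e-6


@dataclass(frozen=True)
class HetModel:
    """Population model: generation interval ``t`` and retention rate ``h``.

    ``h = 0.5`` recovers the classical Mendelian selfing series; the derived
    viability ``u`` and normaliser ``d`` depend on ``r`` and are exposed via
    :meth:`viability`.
    """

    t: int
    h: float

    def __post_init__(self) -> None:
        if int(self.t) != self.t or self.t < 1:
            raise ValueError(f"t must be an integer >= 1, got {self.t}")
        if not 0.0 < self.h < 1.0:
            raise ValueError(f"h must lie in (0, 1), got {self.h}")

    @classmethod
    def from_observed_H(cls, H: float, t: int) -> "HetModel":
        return cls(t=t, h=model.h_from_H(H, t))

    def viability(self, r):
        return model.solve_viability(self.h, r)

    def expected_table(self, r) -> np.ndarray:
        return model.joint_genotype_table(r, self.h, self.t)

    def expected_heterozygosity(self) -> float:
        return model.H_from_h(self.h, self.t)


@dataclass(frozen=True)
class PairCounts:
    """Sufficient statistic for one marker pair: 3x3 genotype-pair counts.

    Fractional tables are allowed so that expected-count tables can be fed to
    the estimator directly (e.g. consistency checks at expectation).
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.float64)
        if t.shape != (3, 3) or not np.all(np.isfinite(t)) or (t < 0).any():
            raise ValueError("counts must be a non-negative 3x3 table")
        object.__setattr__(self, "table", t)

    @property
    def n_informative(self) -> float:
        return float(self.table.sum())


@dataclass(frozen=True)
class RfEstimate:
    r_hat: float
    loglik: float
    n_informative: float


def pair_counts(genotypes_a, genotypes_b) -> PairCounts:
    """Tally genotype pairs, dropping individuals missing at either marker."""
    a = np.asarray(genotypes_a, dtype=np.int8)
    b = np.asarray(genotypes_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    keep = (a != MISSING) & (b != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a[keep], b[keep]), 1)
    return PairCounts(table)


def _require_informative(counts: PairCounts) -> None:
    if counts.n_informative == 0:
        raise ValueError("no informative genotype pairs (n = 0)")


def _require_meiosis(m: HetModel) -> None:
    if m.t < 2:
        raise ValueError("t must be >= 2 to estimate recombination (F1 carries no meiosis)")


def pair_loglik(r, counts: PairCounts, m: HetModel) -> float | np.ndarray:
    """Multinomial log-likelihood of the pair counts at recombination ``r``.

    Accepts scalar or array ``r``.  A cell with zero model probability but a
    positive count yields ``-inf``.
    """
    _require_informative(counts)
    _require_meiosis(m)
    p = m.expected_table(r)
    c = counts.table
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, c * np.log(p), 0.0)
    ll = terms.sum(axis=(-2, -1))
    bad = ((c > 0) & (p <= 0.0)).any(axis=(-2, -1))
    ll = np.where(bad, -np.inf, ll)
    return float(ll) if ll.ndim == 0 else ll


def profile_loglik(counts: PairCounts, m: HetModel, r_grid) -> np.ndarray:
    """Log-likelihood evaluated on an arbitrary grid of ``r`` values."""
    return pair_loglik(np.asarray(r_grid, dtype=float), counts, m)


def estimate_rf(counts: PairCounts, m: HetModel, tol: float = 1e-6) -> RfEstimate:
    """Maximum-likelihood recombination fraction by golden-section search.

    The search maximises :func:`pair_loglik` on the bracket
    ``[1e-6, 0.5 - 1e-6]`` to within ``tol`` on ``r``.  Degenerate tables with
    all counts in a single cell produce a boundary estimate and a warning.
    """
    _require_informative(counts)
    _require_meiosis(m)
    if np.count_nonzero(counts.table) == 1:
        warnings.warn(
            "degenerate pair counts (single occupied cell); "
            "returning a boundary estimate",
            stacklevel=2,
        )

    def f(r: float) -> float:
        return pair_loglik(r, counts, m)

    a, b = _R_LO, _R_HI
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    r_hat = 0.5 * (a + b)
    return RfEstimate(r_hat=float(r_hat), loglik=float(f(r_hat)), n_informative=counts.n_informative)


def haldane_cm(r):
    """Haldane map distance in cM; ``r = 0.5`` maps to ``+inf``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0) or np.any(r > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    with np.errstate(divide="ignore"):
        d = -50.0 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def haldane_r(cm):
    """Inverse Haldane function: map distance in cM to recombination fraction."""
    cm = np.asarray(cm, dtype=float)
    if np.any(cm < 0.0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-cm / 50.0))
    return float(r) if r.ndim == 0 else r


def adjacent_rf_scan(matrix: GenotypeMatrix, m: HetModel, tol: float = 1e-6) -> pd.DataFrame:
    """Estimate ``r`` for every physically adjacent marker pair per chromosome.

    Pairs never span a chromosome boundary.  Pairs with no informative
    individuals are kept with ``r_hat = NaN`` and ``n_informative = 0`` so the
    caller can see and handle them.  Returns a DataFrame with one row per pair:
    chrom, marker_a, marker_b, pos_a, pos_b, n_informative, r_hat, loglik, cm.
    """
    _require_meiosis(m)
    rows = []
    names = matrix.markers.index.to_numpy()
    pos = matrix.markers["pos"].to_numpy()
    for chrom, cols in matrix.chrom_slices().items():
        for j, k in zip(cols[:-1], cols[1:]):
            counts = pair_counts(matrix.geno[:, j], matrix.geno[:, k])
            if counts.n_informative == 0:
                rows.append((chrom, names[j], names[k], pos[j], pos[k], 0, np.nan, np.nan, np.nan))
                continue
            est = estimate_rf(counts, m, tol=tol)
            rows.append(
                (
                    chrom,
                    names[j],
                    names[k],
                    pos[j],
                    pos[k],
                    est.n_informative,
                    est.r_hat,
                    est.loglik,
                    haldane_cm(est.r_hat),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "marker_a",
            "marker_b",
            "pos_a",
            "pos_b",
            "n_informative",
            "r_hat",
            "loglik",
            "cm",
        ],
    )
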