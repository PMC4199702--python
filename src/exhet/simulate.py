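"""Simulation of RIL genotype data under the excess-heterozygosity model.

Two generators live here:

* :func:`simulate_population` — the primary generator.  Markers are equally
  spaced on a linkage group; the genotype sequence of each individual is a
  first-order Markov chain along the chromosome whose marginals and adjacent
  pairwise distributions are exactly those of the genotype-class model at
  ``(r_adjacent, h, t)``.  Data so generated obey precisely the pairwise
  distributions the recombination-fraction estimator assumes; dependence
  beyond adjacent pairs is approximate (first-order).

* :func:`simulate_forward` — an explicitly generation-by-generation selfing
  simulator with zygotic viability selection, used as an independent
  cross-check of the class dynamics at two loci.  It is deliberately separate
  from (and much slower than) the primary generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import model
from .matrix import MISSING, GenotypeMatrix
from .rf import haldane_r

__all__ = ["SimConfig", "simulate_population", "inject_noise", "simulate_forward"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated selfed RIL population.

    Defaults are the reference desk experiment: an F7 population of 1000
    individuals genotyped at 1000 equally spaced markers on a 200-cM linkage
    group with per-generation heterozygosity retention h = 0.6373 (the value
    implied by 6.7% observed heterozygosity at F7) and no noise.  Physical
    positions are synthetic, ``phys_spacing_bp`` apart.
    """

    n_individuals: int = 1000
    n_markers: int = 1000
    map_length_cm: float = 200.0
    t: int = 7
    h: float = 0.6373
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 1
    chrom: str = "1"
    phys_spacing_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("n_individuals and n_markers must be >= 1")
        if self.map_length_cm < 0:
            raise ValueError("map_length_cm must be >= 0")
        if not 0.0 < self.h < 1.0:
            raise ValueError("h must lie in (0, 1)")
        if int(self.t) != self.t or self.t < 1:
            raise ValueError("t must be an integer >= 1")
        for rate in (self.error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def _marker_frame(config: SimConfig) -> pd.DataFrame:
    width = len(str(config.n_markers))
    names = [f"m{j + 1:0{width}d}" for j in range(config.n_markers)]
    pos = 1 + config.phys_spacing_bp * np.arange(config.n_markers)
    return pd.DataFrame({"chrom": config.chrom, "pos": pos}, index=pd.Index(names, name="marker"))


def simulate_population(config: SimConfig) -> GenotypeMatrix:
    """Draw a genotype matrix from the first-order chain of the class model.

    Marker 1 is drawn from the single-locus marginal ``((1-H)/2, H, (1-H)/2)``
    with ``H = h**(t-1)``; each subsequent marker is drawn from the
    conditional of the expected adjacent-pair genotype table given the
    previous marker's genotype.  Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    G = np.empty((n, m), dtype=np.int8)
    H = model.H_from_h(config.h, config.t)
    marginal = np.array([(1.0 - H) / 2.0, H, (1.0 - H) / 2.0])
    G[:, 0] = rng.choice(3, size=n, p=marginal)
    if m > 1:
        r_adj = haldane_r(config.map_length_cm / (m - 1))
        joint = model.joint_genotype_table(r_adj, config.h, config.t)
        cond_cum = np.cumsum(joint / joint.sum(axis=1, keepdims=True), axis=1)
        for j in range(1, m):
            u = rng.random(n)
            G[:, j] = (u[:, None] > cond_cum[G[:, j - 1]]).sum(axis=1)
    matrix = GenotypeMatrix(
        [f"ril{i + 1:04d}" for i in range(n)], _marker_frame(config), G
    )
    if config.error_rate > 0.0 or config.missing_rate > 0.0:
        matrix = inject_noise(matrix, config.error_rate, config.missing_rate, rng)
    return matrix


def inject_noise(matrix: GenotypeMatrix, error_rate: float, missing_rate: float, seed) -> GenotypeMatrix:
    """Apply missingness then symmetric genotyping error to every call.

    Each genotype is independently set to missing with ``missing_rate``; each
    surviving non-missing call is replaced, with ``error_rate``, by one of the
    two other codes chosen uniformly.  ``seed`` may be an int or a Generator.
    """
    for rate in (error_rate, missing_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    G = out.geno
    drop = rng.random(G.shape) < missing_rate
    G[drop] = MISSING
    err = (rng.random(G.shape) < error_rate) & (G != MISSING)
    if err.any():
        # shift by 1 or 2 (mod 3): uniform over the two other codes
        shift = rng.integers(1, 3, size=int(err.sum()))
        G[err] = (G[err] + shift) % 3
    return out


# ---------------------------------------------------------------------------
# Forward-in-time oracle
# ---------------------------------------------------------------------------

_RETRY_CAP = 100_000


def simulate_forward(
    config: SimConfig, selection_mode: str = "class_conditional"
) -> GenotypeMatrix:
    """Generation-by-generation selfing with zygotic viability selection.

    Starting from an all-heterozygous F1, each line advances by single-seed
    descent: two gametes are formed with independent recombination in each
    marker interval (Haldane, no interference), and the offspring is accepted
    by rejection sampling against its viability weight.  Modes:

    ``class_conditional`` (two markers only)
        Faithful to the class model.  Offspring of a double-heterozygous
        parent carry weight ``u**k`` (``k`` = heterozygous loci, ``u`` from
        the viability constraint at the pair's ``r``); offspring of a
        single-heterozygous parent carry weight ``v**k`` with
        ``v = h / (1 - h)``, the weight that retains heterozygosity at rate
        ``h`` at an isolated segregating locus.  This reproduces every column
        of the transition matrix.

    ``per_locus``
        Plain multiplicative viability ``u**k`` for every parent, ``u`` from
        the adjacent-pair constraint.  Only the double-heterozygote columns of
        the transition matrix are matched; kept as the simple multilocus
        viability variant (any number of markers).

    Noise settings in ``config`` are ignored here.  Raises if rejection
    sampling stalls.
    """
    if selection_mode not in ("class_conditional", "per_locus"):
        raise ValueError(f"unknown selection mode {selection_mode!r}")
    m = config.n_markers
    if m < 2:
        raise ValueError("forward simulation needs at least two markers")
    if selection_mode == "class_conditional" and m != 2:
        raise ValueError("class_conditional mode is defined for exactly two markers")
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    r_adj = haldane_r(config.map_length_cm / (m - 1))
    u, _ = model.solve_viability(config.h, r_adj)
    v = config.h / (1.0 - config.h)

    hap1 = np.zeros((n, m), dtype=np.int8)
    hap2 = np.ones((n, m), dtype=np.int8)

    def gametes(h1, h2, size):
        start = rng.integers(0, 2, size=(size, 1), dtype=np.int8)
        flips = (rng.random((size, m - 1)) < r_adj).astype(np.int8)
        path = np.concatenate([start, flips], axis=1).cumsum(axis=1) % 2
        return np.where(path == 0, h1, h2)

    for _ in range(config.t - 1):
        pending = np.arange(n)
        new1 = np.empty_like(hap1)
        new2 = np.empty_like(hap2)
        tries = 0
        while pending.size:
            tries += 1
            if tries > _RETRY_CAP:
                raise RuntimeError("viability rejection sampling stalled")
            h1, h2 = hap1[pending], hap2[pending]
            g1 = gametes(h1, h2, pending.size)
            g2 = gametes(h1, h2, pending.size)
            k_off = (g1 != g2).sum(axis=1)
            k_par = (h1 != h2).sum(axis=1)
            if selection_mode == "per_locus":
                base = np.full(pending.size, u)
            else:
                base = np.where(k_par >= 2, u, v)
            # normalise by the largest attainable weight so acceptance <= 1
            w = base**k_off / np.maximum(base, 1.0) ** k_par
            accept = rng.random(pending.size) < w
            idx = pending[accept]
            new1[idx] = g1[accept]
            new2[idx] = g2[accept]
            pending = pending[~accept]
        hap1, hap2 = new1, new2

    G = (hap1 + hap2).astype(np.int8)  # 0/1/2 == A/H/B
    cfg = replace(config, error_rate=0.0, missing_rate=0.0)
    return GenotypeMatrix(
        [f"ril{i + 1:04d}" for i in range(n)], _marker_frame(cfg), G
    )
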