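"""Two-locus genotype-class dynamics of a selfing population with excess heterozygosity.

A biparental selfed population (recombinant inbred lines, RILs) descends from a
fully heterozygous F1.  For two linked loci with recombination fraction ``r``,
the ten possible genotypes collapse by symmetry into five classes:

========  =====================================  ==========================
class     members                                interpretation
========  =====================================  ==========================
1         ABAB, abab                             parental, fixed
2         AbAb, aBaB                             recombinant, fixed
3         ABaB, Abab, ABAb, aBab                 one locus heterozygous
4         ABab                                   double het, coupling phase
5         AbaB                                   double het, repulsion phase
========  =====================================  ==========================

Selfing is a Markov chain on these classes.  Under Mendelian segregation the
chain is the classical Haldane–Waddington/Bulmer recursion; here each
heterozygous locus retains heterozygosity at a per-generation rate ``h``
(``h = 0.5`` is Mendelian; ``h > 0.5`` is excess heterozygosity, e.g. from a
zygotic viability advantage of heterozygotes).  The population heterozygosity
observed at generation t is ``H = h**(t-1)``.

The class-4/5 columns of the transition matrix follow a zygotic-viability
model in which a genotype heterozygous at a locus has relative viability ``u``
versus either homozygote.  ``u`` is not free: it is pinned, per ``(h, r)``, by
requiring that the heterozygosity retained across one generation from a
double-heterozygous parent equals ``h``.  That constraint is a quadratic in
``u`` with exactly one positive root.

All functions are deterministic and accept either scalar ``r`` or an ndarray
of recombination fractions (broadcast over the leading axes of the result).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "F1_CLASS_DISTRIBUTION",
    "h_from_H",
    "H_from_h",
    "solve_viability",
    "transition_matrix",
    "class_probabilities",
    "joint_genotype_table",
]

#: Class distribution of the F1: every line is the coupling double heterozygote.
F1_CLASS_DISTRIBUTION = np.array([0.0, 0.0, 0.0, 1.0, 0.0])


def _check_h(h: float) -> float:
    h = float(h)
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must lie in (0, 1), got {h}")
    return h


def _check_t(t: int, minimum: int = 1) -> int:
    if int(t) != t or t < minimum:
        raise ValueError(f"t must be an integer >= {minimum}, got {t}")
    return int(t)


def _check_r(r):
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    return arr


def h_from_H(H: float, t: int) -> float:
    """Per-generation heterozygosity retention ``h`` from observed heterozygosity.

    Solves ``H = h**(t-1)`` for ``h``, i.e. ``h = exp(ln(H) / (t - 1))``.

    Parameters
    ----------
    H
        Observed proportion of heterozygous genotypes at generation ``t``,
        strictly between 0 and 1.
    t
        Generation interval (F_t), integer >= 2.
    """
    H = float(H)
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    t = _check_t(t, minimum=2)
    return float(np.exp(np.log(H) / (t - 1)))


def H_from_h(h: float, t: int) -> float:
    """Expected population heterozygosity ``H = h**(t-1)`` at generation ``t``."""
    h = _check_h(h)
    t = _check_t(t, minimum=1)
    return float(h ** (t - 1))


def solve_viability(h: float, r):
    """Heterozygote relative viability ``u`` and normaliser ``d`` for ``(h, r)``.

    From a double-heterozygous parent the offspring class weights are
    ``2(1-r)^2 : 2r^2 : 8ur(1-r) : 2u^2(1-r)^2 : 2u^2 r^2`` (coupling phase;
    classes 1 and 2 swap for repulsion), normalised by

        d = 2(1-r)^2 + 8ur(1-r) + 2r^2 + 2u^2[(1-r)^2 + r^2].

    ``u`` is fixed by requiring the per-locus heterozygosity retained over the
    transition to equal ``h``::

        h = p(class3)/2 + p(class4) + p(class5)

    which rearranges to the quadratic ``2a(h-1)u^2 + b(2h-1)u + 2ah = 0`` with
    ``a = (1-r)^2 + r^2`` and ``b = 4r(1-r)``.  Because the leading coefficient
    is negative and the constant term positive for ``h`` in (0, 1), there is
    exactly one positive root; it is returned.  For ``h = 0.5`` the root is
    ``u = 1`` (no viability differential) at every ``r``.

    Returns
    -------
    (u, d)
        Scalars for scalar ``r``, ndarrays otherwise.
    """
    h = _check_h(h)
    r = _check_r(r)
    a = (1.0 - r) ** 2 + r**2
    b = 4.0 * r * (1.0 - r)
    A = 2.0 * a * (h - 1.0)
    B = b * (2.0 * h - 1.0)
    C = 2.0 * a * h
    disc = B * B - 4.0 * A * C
    if np.any(disc < 0.0):  # pragma: no cover - impossible for h in (0,1)
        raise ArithmeticError("viability quadratic has no real root")
    u = (-B - np.sqrt(disc)) / (2.0 * A)
    if np.any(~np.isfinite(u)) or np.any(u <= 0.0):  # pragma: no cover
        raise ArithmeticError("viability root finding failed")
    d = (
        2.0 * (1.0 - r) ** 2
        + 8.0 * u * r * (1.0 - r)
        + 2.0 * r**2
        + 2.0 * u**2 * ((1.0 - r) ** 2 + r**2)
    )
    if r.ndim == 0:
        return float(u), float(d)
    return u, d


def transition_matrix(r, h: float) -> np.ndarray:
    """One-generation selfing transition matrix over the five genotype classes.

    Column ``j`` is the distribution of offspring classes given parental class
    ``j + 1``.  Classes 1 and 2 are absorbing.  Column 3 is
    ``((1-h)/2, (1-h)/2, h, 0, 0)``: the still-segregating locus retains
    heterozygosity at rate ``h``.  Columns 4 and 5 carry the viability-weighted
    meiosis products of the double heterozygotes (see :func:`solve_viability`).

    Returns a ``(5, 5)`` array for scalar ``r``, ``r.shape + (5, 5)`` otherwise.
    """
    h = _check_h(h)
    r = _check_r(r)
    u, d = solve_viability(h, r)
    u = np.asarray(u, dtype=float)
    d = np.asarray(d, dtype=float)
    rr = np.asarray(r, dtype=float)
    T = np.zeros(rr.shape + (5, 5))
    T[..., 0, 0] = 1.0
    T[..., 1, 1] = 1.0
    T[..., 0, 2] = (1.0 - h) / 2.0
    T[..., 1, 2] = (1.0 - h) / 2.0
    T[..., 2, 2] = h
    par = 2.0 * (1.0 - rr) ** 2 / d  # parental-type fixed offspring
    rec = 2.0 * rr**2 / d  # recombinant-type fixed offspring
    single = 8.0 * u * rr * (1.0 - rr) / d
    T[..., 0, 3] = par
    T[..., 1, 3] = rec
    T[..., 2, 3] = single
    T[..., 3, 3] = u**2 * par
    T[..., 4, 3] = u**2 * rec
    T[..., 0, 4] = rec
    T[..., 1, 4] = par
    T[..., 2, 4] = single
    T[..., 3, 4] = u**2 * rec
    T[..., 4, 4] = u**2 * par
    return T


def class_probabilities(r, h: float, t: int) -> np.ndarray:
    """Genotype-class distribution at generation ``t``.

    Applies the transition matrix ``t - 1`` times to the F1 distribution
    ``(0, 0, 0, 1, 0)``.  Iteration is exact to machine precision for any
    practical ``t`` and avoids a closed-form eigendecomposition.

    Returns a length-5 vector for scalar ``r``, ``r.shape + (5,)`` otherwise.
    """
    t = _check_t(t, minimum=1)
    r = _check_r(r)
    T = transition_matrix(r, h)
    p = np.broadcast_to(F1_CLASS_DISTRIBUTION, np.asarray(r).shape + (5,)).copy()
    for _ in range(t - 1):
        p = np.einsum("...ij,...j->...i", T, p)
    return p


def joint_genotype_table(r, h: float, t: int) -> np.ndarray:
    """Expected 3x3 table of observable genotype pairs at generation ``t``.

    Rows index the genotype at the first locus (AA, Aa, aa) and columns the
    second (BB, Bb, bb).  The five symmetry classes unfold assuming the members
    of each class are equiprobable (the selfing symmetry that justifies the
    class collapse in the first place); the two double-heterozygote phases are
    observationally indistinguishable and merge into the centre cell.

    Both marginals put probability ``h**(t-1)`` on the heterozygote.
    """
    p = class_probabilities(r, h, t)
    J = np.zeros(p.shape[:-1] + (3, 3))
    J[..., 0, 0] = p[..., 0] / 2.0
    J[..., 2, 2] = p[..., 0] / 2.0
    J[..., 0, 2] = p[..., 1] / 2.0
    J[..., 2, 0] = p[..., 1] / 2.0
    J[..., 1, 0] = p[..., 2] / 4.0
    J[..., 1, 2] = p[..., 2] / 4.0
    J[..., 0, 1] = p[..., 2] / 4.0
    J[..., 2, 1] = p[..., 2] / 4.0
    J[..., 1, 1] = p[..., 3] + p[..., 4]
    return J
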