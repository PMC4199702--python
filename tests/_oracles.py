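"""Independent reference implementations used only to cross-check the package."""

from itertools import groupby

import numpy as np


def mendelian_class_probabilities(r: float, t: int) -> np.ndarray:
    """Classical Mendelian two-locus selfing recursion (Haldane-Waddington).

    Coded independently of the package: the transition columns are written
    out with the textbook values (no viability term, normaliser 4).
    """
    col3 = np.array([0.25, 0.25, 0.5, 0.0, 0.0])
    col4 = np.array(
        [(1 - r) ** 2 / 2, r**2 / 2, 2 * r * (1 - r), (1 - r) ** 2 / 2, r**2 / 2]
    )
    col5 = col4[[1, 0, 2, 4, 3]]
    T = np.column_stack(
        [
            [1, 0, 0, 0, 0],
            [0, 1, 0, 0, 0],
            col3,
            col4,
            col5,
        ]
    )
    p = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    for _ in range(t - 1):
        p = T @ p
    return p


def mendelian_joint_table(r: float, t: int) -> np.ndarray:
    """Observable 3x3 genotype-pair table under the Mendelian recursion."""
    p1, p2, p3, p4, p5 = mendelian_class_probabilities(r, t)
    return np.array(
        [
            [p1 / 2, p3 / 4, p2 / 2],
            [p3 / 4, p4 + p5, p3 / 4],
            [p2 / 2, p3 / 4, p1 / 2],
        ]
    )


def mask_double_recombinants_reference(genotypes, positions, window):
    """Brute-force double-recombination masking for one individual.

    Works on the non-missing subsequence with itertools.groupby and repeats
    until nothing changes.
    """
    g = list(genotypes)
    while True:
        obs = [i for i, x in enumerate(g) if x != -1]
        runs = []
        for _, grp in groupby(obs, key=lambda i: g[i]):
            grp = list(grp)
            runs.append((grp[0], grp[-1]))
        to_mask = set()
        for k in range(1, len(runs) - 1):
            left = runs[k - 1][1]
            right = runs[k + 1][0]
            if g[left] == g[right] and positions[right] - positions[left] <= window:
                s, e = runs[k]
                to_mask.update(i for i in obs if s <= i <= e)
        if not to_mask:
            return g
        for i in to_mask:
            g[i] = -1
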