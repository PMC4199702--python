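import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exhet import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(geno, chroms=None, positions=None, individuals=None):
    """Small-matrix helper: geno is a list of per-individual code lists."""
    geno = np.asarray(geno, dtype=np.int8)
    n_ind, n_mark = geno.shape
    chroms = chroms if chroms is not None else ["1"] * n_mark
    positions = positions if positions is not None else [1 + 1000 * j for j in range(n_mark)]
    markers = pd.DataFrame(
        {"chrom": [str(c) for c in chroms], "pos": positions},
        index=pd.Index([f"m{j + 1}" for j in range(n_mark)], name="marker"),
    )
    individuals = individuals if individuals is not None else [f"i{k + 1}" for k in range(n_ind)]
    return GenotypeMatrix(individuals, markers, geno)


@pytest.fixture
def tiny_matrix():
    return make_matrix(
        [
            [0, 0, 1, 2],
            [1, -1, 2, 2],
            [2, 0, 0, -1],
        ]
    )
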