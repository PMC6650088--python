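import numpy as np
import pytest

from tci.types import BinaryEventMatrix, Cohort


def make_cohort(sga, deg, tissues=None, sga_genes=None, deg_genes=None):
    """Small-cohort helper: build a Cohort from 0/1 array-likes."""
    sga = np.asarray(sga)
    deg = np.asarray(deg)
    n = sga.shape[0]
    tumors = [f"t{i + 1}" for i in range(n)]
    sga_genes = sga_genes or [f"A{j + 1}" for j in range(sga.shape[1])]
    deg_genes = deg_genes or [f"E{j + 1}" for j in range(deg.shape[1])]
    tissues = tissues or ["brca"] * n
    return Cohort(
        sga=BinaryEventMatrix(sga, tumors, sga_genes),
        deg=BinaryEventMatrix(deg, tumors, deg_genes),
        tissue=dict(zip(tumors, tissues)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
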