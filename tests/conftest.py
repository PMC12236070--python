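import warnings

import numpy as np
import pytest

from pathcell import (AucellParams, ExpressionMatrix, GeneSet, SyntheticSpec,
                      simulate_dataset, simulate_ontology)

warnings.filterwarnings("ignore", message="n_pcs lowered")
warnings.filterwarnings("ignore", message=".*force_all_finite.*")


@pytest.fixture(scope="session")
def small_bundle():
    """300-cell, 600-gene planted dataset shared across tests."""
    spec = SyntheticSpec(n_cells=300, n_genes=600, seed=3)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def toy_ontology():
    """2-branch, depth-3 ontology with leaf gene sets (no obsolete terms)."""
    return simulate_ontology(n_branches=2, depth=3, seed=0)


@pytest.fixture()
def tiny_expr():
    """4 genes x 3 cells with distinct values, no ties."""
    values = np.array([
        [9.0, 1.0, 4.0],
        [7.0, 2.0, 3.0],
        [5.0, 8.0, 2.0],
        [3.0, 6.0, 1.0],
    ])
    return ExpressionMatrix(values, ["g1", "g2", "g3", "g4"], ["c1", "c2", "c3"])


@pytest.fixture()
def stable_params():
    return AucellParams(top_fraction=0.5, tie_rule="stable_index")


def write_gmt(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path
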