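import numpy as np
import pytest

from watblocks.blocks import AssociationParams
from watblocks.fragments import ClassifierTable, step_torsions
from watblocks.synthetic import (SyntheticSpec, default_planted_sites,
                                 make_corpus, make_ideal_step)

#: Minimal hand-written 2-residue DNA fixture (no waters).
TWO_RES_PDB = """\
ATOM      1  O5' DG  A   1       1.000   2.000   3.000  1.00 10.00           O
ATOM      2  C5' DG  A   1       2.000   2.500   3.000  1.00 10.00           C
ATOM      3  C4' DG  A   1       3.000   3.000   3.500  1.00 10.00           C
ATOM      4  C3' DG  A   1       4.000   3.200   2.800  1.00 10.00           C
ATOM      5  O3' DG  A   1       5.000   3.500   3.200  1.00 10.00           O
ATOM      6  C1' DG  A   1       3.500   4.500   3.900  1.00 10.00           C
ATOM      7  N9  DG  A   1       3.800   5.500   4.500  1.00 10.00           N
ATOM      8  P   DC  A   2       5.900   4.500   3.900  1.00 10.00           P
ATOM      9  O5' DC  A   2       6.900   4.000   4.500  1.00 10.00           O
ATOM     10  C5' DC  A   2       7.900   4.800   4.900  1.00 10.00           C
ATOM     11  C4' DC  A   2       8.900   5.000   5.500  1.00 10.00           C
ATOM     12  C1' DC  A   2       9.500   6.200   5.900  1.00 10.00           C
ATOM     13  N1  DC  A   2       9.800   7.200   6.400  1.00 10.00           N
END
"""

THREE_WATERS = """\
HETATM   21  O   HOH A 101       2.000   6.000   8.000  1.00 20.00           O
HETATM   22  O   HOH A 102      12.000   6.000   8.000  1.00 20.00           O
HETATM   23  O   DOD A 103       2.000  16.000   8.000  1.00 20.00           O
"""


@pytest.fixture(scope="session")
def ideal_step():
    return make_ideal_step("GC", "B")


@pytest.fixture(scope="session")
def planted_sites(ideal_step):
    return default_planted_sites(ideal_step)


@pytest.fixture(scope="session")
def bb00_classifier(ideal_step):
    """One-centroid classifier labelling the ideal B-form GC step BB00."""
    return ClassifierTable(centroids={"BB00": step_torsions(ideal_step).values})


@pytest.fixture(scope="session")
def small_corpus(ideal_step, planted_sites):
    """40 rigidly scattered copies of the ideal step with planted hydration."""
    spec = SyntheticSpec(n_structures=40, seq2="GC", seed=7,
                         planted_sites=planted_sites)
    return make_corpus(spec)


@pytest.fixture
def assoc_params():
    return AssociationParams(min_waters_reliable=50)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
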