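import numpy as np
import pytest

from sipgcn.graph_fastgcn import ProteinGraph, build_knn_graph
from sipgcn.io_formats import PSSMMatrix
from sipgcn.synthetic_data import SyntheticSpec, generate_records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pssm_text():
    """A 3-row PSI-BLAST-style profile: 4 on the diagonal A/C/D cells."""
    header = "A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V".split()
    rows = []
    for i, res in enumerate("ACD", start=1):
        scores = [0] * 20
        scores[header.index(res)] = 4
        rows.append(f"{i:5d} {res} " + " ".join(f"{s:3d}" for s in scores))
    return "\n".join(
        [
            "",
            "Last position-specific scoring matrix computed, weighted, observed...",
            "            " + " ".join(header),
            *rows,
            "",
        ]
    )


@pytest.fixture
def random_pssm(rng):
    """A random 50-residue integer profile with standard residues."""
    from sipgcn.io_formats import PSIBLAST_COLUMN_ORDER

    n = 50
    letters = np.array(list(PSIBLAST_COLUMN_ORDER))
    seq = "".join(letters[rng.integers(0, 20, size=n)])
    scores = rng.integers(-8, 9, size=(n, 20)).astype(float)
    return PSSMMatrix(scores=scores, residues=seq)


@pytest.fixture
def six_node_graph(rng):
    """A fixed small graph for Monte-Carlo estimator checks."""
    X = rng.normal(size=(6, 4)) + 1.5
    return build_knn_graph(X, k=2)


@pytest.fixture
def separable_graph(rng):
    """Two well-separated Gaussian feature clusters on a kNN graph."""
    X = np.vstack(
        [
            rng.normal(0, 0.3, size=(30, 5)) + np.array([2, 0, 0, 0, 0]),
            rng.normal(0, 0.3, size=(30, 5)) + np.array([0, 2, 0, 0, 0]),
        ]
    )
    y = np.array([1] * 30 + [0] * 30)
    return build_knn_graph(X, k=5, labels=y)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-shift dataset shared across tests (in memory)."""
    spec = SyntheticSpec(n_pos=30, n_neg=30, length_range=(50, 120), shift=3.0, seed=42)
    return generate_records(spec)
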