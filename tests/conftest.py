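import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from scina import ExpressionMatrix, SignatureSet


@pytest.fixture
def tiny_expr():
    """4 genes x 6 cells; g1/g2 high in the first three cells, g3/g4 in the rest."""
    rng = np.random.default_rng(42)
    high = rng.normal(4.0, 0.3, size=(2, 3))
    low = rng.normal(0.0, 0.3, size=(2, 3))
    values = np.block([[high, low], [low, high]])
    return ExpressionMatrix(
        gene_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(6)], dtype=object),
        values=values,
    )


@pytest.fixture
def tiny_sigs():
    return SignatureSet({"alpha": ["g1", "g2"], "beta": ["g3", "g4"]})
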