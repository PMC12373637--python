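import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from enrichmap.datatypes import ExpressionMatrix, GeneSet, GeneSetDatabase, RankedList


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with a two-class assignment."""
    counts = pd.DataFrame(
        [[10.0, 20.0, 30.0, 40.0], [5.0, 5.0, 5.0, 5.0], [0.0, 1.0, 2.0, 3.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(counts, {"S1": "A", "S2": "A", "S3": "B", "S4": "B"})


@pytest.fixture
def toy_ranks() -> RankedList:
    """Five genes scored (3, 2, 1, -1, -2)."""
    return RankedList(
        [("G1", 3.0), ("G2", 2.0), ("G3", 1.0), ("G4", -1.0), ("G5", -2.0)]
    )


@pytest.fixture
def toy_db() -> GeneSetDatabase:
    return GeneSetDatabase(
        [
            GeneSet("SETA", "first", frozenset({"TP53", "BRCA1"})),
            GeneSet("SETB", "second", frozenset({"EGFR"})),
        ]
    )


def random_ranked_list(rng: np.random.Generator, n: int) -> RankedList:
    genes = [f"G{i:03d}" for i in range(n)]
    scores = rng.normal(size=n)
    return RankedList(zip(genes, scores))
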