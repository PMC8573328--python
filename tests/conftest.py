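import numpy as np
import pandas as pd
import pytest

from invgsea import ExpressionMatrix, SimDesign, simulate_two_contrast_counts
from invgsea.dge import RankedList


def two_group_matrix(counts: pd.DataFrame) -> ExpressionMatrix:
    """Wrap a simulated counts frame; columns follow the *_{ctrl,trt}_i scheme."""
    gm = {c: ("trt" if "_trt_" in c else "ctrl") for c in counts.columns}
    return ExpressionMatrix(counts, gm)


@pytest.fixture
def toy_ranked() -> RankedList:
    """Five genes, metric 3, 2, 1, -1, -3 — the hand-enumerated worked example."""
    return RankedList(
        np.array(["g1", "g2", "g3", "g4", "g5"], dtype=object),
        np.array([3.0, 2.0, 1.0, -1.0, -3.0]),
    )


@pytest.fixture(scope="session")
def standard_contrast():
    """The standard synthetic design (seed 7) with both contrast matrices."""
    design = SimDesign(
        n_genes=2000, n_de=200, lfc_magnitude=1.0, dispersion=0.1,
        n_samples_per_group=6, inversion_fraction=0.5, seed=7,
    )
    counts_a, counts_b, truth = simulate_two_contrast_counts(design)
    return design, two_group_matrix(counts_a), two_group_matrix(counts_b), truth
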