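import numpy as np
import pandas as pd
import pytest

from flycerna.diffexpr import CountMatrix
from flycerna.simdata import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def small_config():
    """A small but fully-featured synthetic study design."""
    return SimulationConfig(
        n_mrna=12, n_lncrna=4, n_circrna=4, n_mirna=6, n_triples_planted=4,
        utr_length=200, sponge_length=250, seed=7,
    )


def make_count_matrix(values: dict[str, list[int]], conditions: list[str]):
    """Tiny CountMatrix helper: values maps sample -> counts column."""
    counts = pd.DataFrame(values)
    design = pd.DataFrame(
        {
            "condition": conditions,
            "assay": ["rnaseq"] * len(conditions),
            "replicate": list(range(1, len(conditions) + 1)),
        },
        index=list(values),
    )
    return CountMatrix(counts, design)
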