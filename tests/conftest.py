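import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from lactopan import PAVMatrix, SyntheticANISpec, generate_ani_inputs


def random_pav(rng: np.random.Generator, n_genomes: int, n_genes: int) -> PAVMatrix:
    """Random binary matrix with every gene carried by >=1 genome."""
    arr = (rng.random((n_genomes, n_genes)) < rng.uniform(0.15, 0.85)).astype(np.int8)
    empty = arr.sum(axis=0) == 0
    for j in np.nonzero(empty)[0]:
        arr[rng.integers(n_genomes), j] = 1
    return PAVMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i:02d}" for i in range(n_genomes)],
            columns=[f"gene{j:04d}" for j in range(n_genes)],
        )
    )


@pytest.fixture
def small_pav():
    rng = np.random.default_rng(42)
    return random_pav(rng, 6, 40)


@pytest.fixture
def planted_ani():
    spec = SyntheticANISpec(cluster_sizes=[4, 3, 5], seed=7)
    return generate_ani_inputs(spec)
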