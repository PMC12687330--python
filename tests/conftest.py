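import numpy as np
import pandas as pd
import pytest

from stagedev.containers import CountMatrix
from stagedev.simulate import SyntheticSpec, generate_counts


@pytest.fixture(scope="session")
def toy_counts() -> CountMatrix:
    """3 genes x 2 samples with hand-checkable numbers."""
    counts = pd.DataFrame(
        {"s1": [10, 0, 90], "s2": [30, 5, 65]},
        index=["gA", "gB", "gC"],
    )
    samples = pd.DataFrame(
        {
            "species": ["sp", "sp"],
            "stage": ["1", "5"],
            "phase": ["embryonic", "embryonic"],
            "library_size": [100, 100],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    lengths = pd.Series([100, 200, 400], index=counts.index, name="length_bp")
    return CountMatrix(counts, samples, lengths)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic dataset (500 genes), with truth tables."""
    spec = SyntheticSpec(n_genes=500, seed=11)
    cm, truth = generate_counts(spec)
    return spec, cm, truth


@pytest.fixture(scope="session")
def replicate_dataset():
    """5 stages x 2 replicates, no planted effects: for dispersion oracles."""
    spec = SyntheticSpec(
        n_genes=2000, phi=0.36, seed=5,
        stage_labels=("1", "5", "8", "13", "17"),
        post_embryonic_labels=(), n_replicates=2,
        deg_fraction=0.0, archetype_fraction=0.0, orphan_fraction=0.0,
    )
    cm, truth = generate_counts(spec)
    return spec, cm, truth
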