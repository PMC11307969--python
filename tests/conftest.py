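import numpy as np
import pandas as pd
import pytest

import pdxkit as pk


@pytest.fixture(scope="session")
def separable_cfg() -> pk.SimulationConfig:
    """The shipped separable study conditions: 3 classes, effect 4, noise 0.5."""
    return pk.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def separable_cohort(separable_cfg):
    return pk.make_reference_cohort(separable_cfg)


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "max_transcript_length": [1000, 500, 2000, 1500],
            "is_coding": [True, True, True, False],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )


@pytest.fixture()
def toy_counts() -> pk.ExpressionMatrix:
    data = pd.DataFrame(
        {"s1": [1000.0, 50.0, 0.0], "s2": [10.0, 20.0, 30.0]},
        index=["g1", "g2", "g3"],
    )
    return pk.ExpressionMatrix(data, unit="counts")


def random_integer_cohort(seed: int):
    """A tiny random cohort with frequent rank ties, for oracle checks.

    Returns (query Series, reference DataFrame, labels Series, k); all
    columns are guaranteed non-constant.
    """
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, 7))
    n_ref = int(rng.integers(2, 9))

    def column():
        while True:
            col = rng.integers(0, 10, size=n_genes).astype(float)
            if np.ptp(col) > 0:
                return col

    reference = pd.DataFrame(
        {f"r{i:02d}": column() for i in range(n_ref)},
        index=[f"g{j}" for j in range(n_genes)],
    )
    query = pd.Series(column(), index=reference.index, name="q")
    n_classes = int(rng.integers(1, 4))
    labels = pd.Series(
        rng.choice([f"C{c}" for c in range(n_classes)], size=n_ref),
        index=reference.columns,
    )
    k = int(rng.integers(1, n_ref + 1))
    return query, reference, labels, k
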