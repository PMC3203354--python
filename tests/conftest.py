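import numpy as np
import pandas as pd
import pytest

from sigsearch import ExpressionDataset, Signature, znormalize


@pytest.fixture
def sig33():
    return Signature("s33", up=frozenset(["A", "B", "C"]), down=frozenset(["D", "E", "F"]))


@pytest.fixture
def sig2020():
    return Signature(
        "s2020",
        up=frozenset(f"U{i:02d}" for i in range(20)),
        down=frozenset(f"W{i:02d}" for i in range(20)),
    )


def make_dataset(
    n_genes=30,
    n_samples=8,
    dataset_id="DS1",
    platform_id="P1",
    seed=0,
    genes=None,
    normalized=True,
):
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:03d}" for i in range(n_genes)]
    values = pd.DataFrame(
        rng.standard_normal((len(genes), n_samples)),
        index=genes,
        columns=[f"S{i:02d}" for i in range(n_samples)],
    )
    ds = ExpressionDataset(dataset_id=dataset_id, platform_id=platform_id, values=values)
    return znormalize(ds) if normalized else ds


@pytest.fixture
def dataset_factory():
    return make_dataset
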