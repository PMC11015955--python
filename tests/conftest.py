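import numpy as np
import pytest

from grmec.ensemble import from_label_vectors
from grmec.io import LabelVector, MultiOmicsDataset, OmicsMatrix


def make_random_instance(seed, n=100, m=2, q=2, p=(40, 30), C=3):
    """A random multi-view instance with random base partitions (no structure)."""
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n)]
    views = [
        OmicsMatrix(
            rng.uniform(size=(n, pv)),
            cells,
            [f"v{v}f{j}" for j in range(pv)],
            f"view{v}",
        )
        for v, pv in enumerate(p)
    ]
    grid = [
        [LabelVector(rng.integers(0, C, size=n), cells) for _ in range(m)]
        for _ in range(q)
    ]
    return MultiOmicsDataset(views), from_label_vectors(grid)


@pytest.fixture
def tiny_view():
    """5 cells x 4 features, nonnegative, with distinct variability."""
    rng = np.random.default_rng(7)
    X = rng.uniform(0, 5, size=(5, 4))
    return OmicsMatrix(X, [f"c{i}" for i in range(5)], list("abcd"), "rna")


@pytest.fixture
def blob_dataset():
    """3 well-separated nonnegative blobs in two views, with truth labels."""
    from grmec.simulate import SimConfig, simulate_multiomics

    sim = simulate_multiomics(
        SimConfig(n=90, C=3, m=2, p=(40, 25), separation=3.0, dropout_rate=0.0, seed=11)
    )
    return sim
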