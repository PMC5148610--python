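import numpy as np
import pytest

import oplconn as oc


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset (three BC types) with features
    extracted; shared across tests that only read from it."""
    cfg = oc.OplSimConfig(seed=11)
    ds = oc.generate_dataset(cfg, bc_types=["CBC6", "CBC9", "RBC"], with_sac=False)
    oc.extract_dataset_features(ds)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_skeleton(rng, n_nodes=30, cell_id="cell"):
    """Random tree skeleton: each node's parent is a random earlier node."""
    xyz = rng.uniform(-10, 10, (n_nodes, 3))
    parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n_nodes)]
    ids = np.arange(1, n_nodes + 1)
    parent_ids = np.array([p + 1 if p >= 0 else -1 for p in parents])
    return oc.Skeleton(ids, parent_ids, xyz, np.full(n_nodes, 0.3), cell_id=cell_id)
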