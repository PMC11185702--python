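import numpy as np
import pandas as pd
import pytest

from neckcompare import (
    GeneratorConfig,
    TreeSkeleton,
    generate_connectome,
    recovery_config,
    smoke_config,
)
from neckcompare import pipeline as pl


def make_skeleton(coords, parents, neuron_id="n", radius=200.0):
    """TreeSkeleton from an (n, 3) coordinate array and 0-based parent list."""
    coords = np.asarray(coords, dtype=float)
    n = len(parents)
    df = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "parent_id": [(-1 if p < 0 else p + 1) for p in parents],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "radius": radius,
            "label": 0,
        }
    )
    return TreeSkeleton(neuron_id=neuron_id, nodes=df)


def random_tree(rng, n_nodes=30, scale_nm=30_000.0, neuron_id="n"):
    """Random tree: each node attaches to a random earlier node."""
    coords = [rng.uniform(0, scale_nm, 3)]
    parents = [-1]
    for i in range(1, n_nodes):
        p = int(rng.integers(0, i))
        step = rng.normal(0, scale_nm / 8, 3)
        coords.append(coords[p] + step)
        parents.append(p)
    return make_skeleton(np.array(coords), parents, neuron_id=neuron_id)


@pytest.fixture(scope="session")
def smoke_connectome():
    return generate_connectome(smoke_config(seed=11))


@pytest.fixture(scope="session")
def recovery_run():
    """Recovery fixture (60 types, planted specials) with the full pipeline run."""
    sc = generate_connectome(recovery_config(seed=7))
    lr_f = pl.run_lr_pairing(sc, "F")
    lr_m = pl.run_lr_pairing(sc, "M")
    cross = pl.run_cross_matching(sc)
    return {"sc": sc, "lr_f": lr_f, "lr_m": lr_m, "cross": cross}
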