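import numpy as np
import pandas as pd
import pytest

import fvrin as fv


@pytest.fixture(scope="session")
def helix12():
    """12-residue ideal alpha-helix (phi=-57, psi=-47)."""
    return fv.generate_toy_structure(12, torsions=(-57.0, -47.0), seed=0)


@pytest.fixture(scope="session")
def helix_rin(helix12):
    return fv.build_rin(helix12)


@pytest.fixture(scope="session")
def er_graph30():
    """Seeded Erdős–Rényi graph for centrality oracle checks."""
    return fv.generate_random_graph(30, "erdos_renyi", {"p": 0.15}, seed=42)


@pytest.fixture(scope="session")
def centrality_cloud():
    """Random (degree, betweenness, closeness) table spanning printed-scale ranges."""
    rng = np.random.default_rng(11)
    n = 500
    degree = rng.integers(2, 14, size=n).astype(float)
    degree[0], degree[1] = 2.0, 13.0  # pin the observed range
    betweenness = 10.0 ** rng.uniform(-0.48, 4.977, size=n)
    closeness = rng.uniform(0.05, 0.9, size=n)
    return pd.DataFrame(
        {"degree": degree, "betweenness": betweenness, "closeness": closeness}
    )
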