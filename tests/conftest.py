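import numpy as np
import pandas as pd
import pytest

from palscreen.pathway_graph import Edge, InteractionType, PathwayCollection


@pytest.fixture
def toy_collection() -> PathwayCollection:
    """Two small pathways sharing node A."""
    return PathwayCollection(
        {
            "P1": [
                Edge("A", "C", InteractionType.ACTIVATION),
                Edge("C", "B", InteractionType.INHIBITION),
                Edge("D", "E", InteractionType.ACTIVATION),
            ],
            "P2": [Edge("A", "F", InteractionType.BINDING_ASSOCIATION)],
        }
    )


def random_collection(rng: np.random.Generator, n_nodes: int = 20, n_edges: int = 40) -> PathwayCollection:
    nodes = [f"N{i}" for i in range(n_nodes)]
    types = list(InteractionType)
    pathways: dict[str, list[Edge]] = {"P1": [], "P2": []}
    for _ in range(n_edges):
        u, v = rng.choice(nodes, size=2, replace=False)
        t = types[rng.integers(len(types))]
        pathways[["P1", "P2"][rng.integers(2)]].append(Edge(u, v, t))
    return PathwayCollection(pathways)


@pytest.fixture
def small_cohort() -> pd.DataFrame:
    """Deterministic 6-gene × 4-sample count matrix."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.poisson(100, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(4)],
    )
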