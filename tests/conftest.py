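import numpy as np
import pandas as pd
import pytest

from grnsign.expression import ExpressionCompendium
from grnsign.network import Edge, RegulatoryNetwork


@pytest.fixture
def triangle_net() -> RegulatoryNetwork:
    """A -> B (activation), A -> C (repression), B -> C (activation)."""
    return RegulatoryNetwork(
        set(), [Edge("A", "B", 1), Edge("A", "C", -1), Edge("B", "C", 1)]
    )


def random_network(rng: np.random.Generator, n_nodes: int, n_edges: int) -> RegulatoryNetwork:
    """A random simple signed digraph (no duplicate pairs, self-loops allowed)."""
    nodes = [f"g{i}" for i in range(n_nodes)]
    pairs = [(u, v) for u in nodes for v in nodes]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    edges = [
        Edge(pairs[i][0], pairs[i][1], int(rng.choice([-1, 1]))) for i in idx
    ]
    return RegulatoryNetwork(set(nodes), edges)


def random_labels(rng: np.random.Generator, genes: list[str], n_contrasts: int) -> pd.DataFrame:
    return pd.DataFrame(
        rng.integers(-1, 2, size=(len(genes), n_contrasts)).astype(np.int8),
        index=genes,
        columns=[f"c{i}" for i in range(n_contrasts)],
    )


def small_compendium(rng: np.random.Generator, n_genes: int = 8, per_dataset: int = 4,
                     n_datasets: int = 2) -> ExpressionCompendium:
    genes = [f"g{i}" for i in range(n_genes)]
    cols, meta = {}, []
    for d in range(n_datasets):
        for s in range(per_dataset):
            name = f"d{d}s{s}"
            cols[name] = rng.normal(size=n_genes)
            meta.append({"sample": name, "dataset": f"d{d}",
                         "platform": "microarray" if d % 2 == 0 else "rnaseq"})
    return ExpressionCompendium(
        pd.DataFrame(cols, index=genes), pd.DataFrame(meta).set_index("sample")
    )
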