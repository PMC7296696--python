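import numpy as np
import pytest

from sscentrality import from_edge_list


@pytest.fixture
def path_graph():
    """The canonical 3-node path a -> b -> c."""
    return from_edge_list([("a", "b"), ("b", "c")], "path3")


@pytest.fixture
def two_cycle():
    return from_edge_list([("a", "b"), ("b", "a")], "cycle2")


def random_graph(rng: np.random.Generator, n_max: int = 50, p: float | None = None,
                 pathway_id: str = "rand"):
    """Random simple directed graph with 2..n_max nodes, no self-loops."""
    n = int(rng.integers(2, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.05, 0.4))
    names = [f"v{i}" for i in range(n)]
    rows = []
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    for i in range(n):
        for j in range(n):
            if mask[i, j]:
                rows.append((names[i], names[j]))
    return from_edge_list(rows, pathway_id=pathway_id, nodes=names)


def make_filter_fixture():
    """20 pathways engineered to exercise every quality-filter rule.

    Returns (graphs, important gene set, expected) where expected maps
    pathway_id -> (decision, reason).
    """
    from sscentrality import GeneSet, SyntheticSpec, generate_cohort

    graphs, expected = [], {}
    important: set[str] = set()

    # 12 pathways that pass every rule: layered DAGs with 6 planted genes
    cohort = generate_cohort(
        SyntheticSpec(n_pathways=12, seed=123, importance_model="uniform",
                      importance_rate=0.5)
    )
    for g in cohort.graphs:
        graphs.append(g)
        important.update(g.nodes[:6])
        expected[g.pathway_id] = ("kept", "none")

    # oversized: >1000 nodes AND >4000 edges (chain + skips + a clique)
    names = [f"big{i}" for i in range(1001)]
    rows = [(names[i], names[i + k]) for k in (1, 2, 3, 4) for i in range(1001 - k)]
    rows += [(names[i], names[j]) for i in range(25) for j in range(25) if i != j]
    graphs.append(__import__("sscentrality").from_edge_list(rows, "huge"))
    expected["huge"] = ("excluded", "too_large")

    from sscentrality import from_edge_list

    # undersized by nodes: a 10-node path
    p10 = [(f"s{i}", f"s{i+1}") for i in range(9)]
    graphs.append(from_edge_list(p10, "tiny_nodes"))
    expected["tiny_nodes"] = ("excluded", "too_small")

    # undersized by edges: 30 nodes but exactly 20 edges
    p21 = [(f"t{i}", f"t{i+1}") for i in range(20)]
    graphs.append(
        from_edge_list(p21, "tiny_edges", nodes=[f"iso{i}" for i in range(9)])
    )
    expected["tiny_edges"] = ("excluded", "too_small")

    # spectrally extreme: a 12-clique (lambda_1 = 11) plus a 21-node tail
    clique = [(f"k{i}", f"k{j}") for i in range(12) for j in range(12) if i != j]
    tail = [("k0", "w0")] + [(f"w{i}", f"w{i+1}") for i in range(20)]
    graphs.append(from_edge_list(clique + tail, "spiky"))
    expected["spiky"] = ("excluded", "eigenvalue")

    # vertex-transitive ring: every centrality is constant
    ring = [(f"r{i}", f"r{(i+1) % 30}") for i in range(30)]
    graphs.append(from_edge_list(ring, "ring"))
    expected["ring"] = ("excluded", "constant_centrality")

    # well-formed pathways with too few important genes (5, 3, 0)
    extra = generate_cohort(
        SyntheticSpec(n_pathways=15, seed=321, importance_model="uniform",
                      importance_rate=0.5)
    )
    for g, k in zip(extra.graphs[12:15], (5, 3, 0)):
        graphs.append(g)
        important.update(g.nodes[:k])
        expected[g.pathway_id] = ("excluded", "too_few_important")

    assert len(graphs) == 20
    return graphs, GeneSet("fixture_important", frozenset(important)), expected


def contraction_graph(rng: np.random.Generator, n_max: int = 30):
    """Random graph paired with a Katz-admissible alpha (alpha * rho < 1)."""
    from sscentrality import spectral_radius

    g = random_graph(rng, n_max=n_max)
    rho = spectral_radius(g)
    alpha = float(rng.uniform(0.05, 0.9)) / max(rho, 1.0)
    return g, alpha
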