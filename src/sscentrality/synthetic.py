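"""Synthetic layered pathway graphs with planted important genes.

Signaling pathways have an upstream-to-downstream organisation: a small set
of receptor-like elements fans signal out into a broader body of
intermediate transducers, which converge onto a small set of effector-like
terminal elements.  The generator emulates exactly this shape: each
pathway is a layered DAG whose first and last layers are narrow
(bottlenecks) and densely wired to their adjacent layers, while middle
layers are wider and sparsely wired.  Layer-skipping forward edges and an
optional trickle of feedback edges (to exercise cyclic solvers) can be
added.

Three planting schemes place the a-priori "important" genes:

``terminal_ends``
    important genes concentrate in the first and last layers (rate
    ``importance_rate``) with a background rate of a quarter of that in the
    middle — the regime in which source-only and sink-only centralities
    each see only half of the signal while their sum sees all of it.
``hubs``
    important genes are drawn from the degree-boosted hub nodes.
``uniform``
    importance is i.i.d. over all nodes — the null regime with no
    topological signal.

Cohorts are fully deterministic given the spec's seed; each pathway uses a
derived seed (``seed + pathway index``) so a cohort is stable under changes
of ``n_pathways``.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .graph import PathwayGraph, from_edge_list, read_edge_list
from .pathway_io import GeneSet, read_gene_set, write_gene_sets_gmt

__all__ = ["SyntheticSpec", "SyntheticCohort", "generate_cohort", "expected_signal",
           "write_cohort", "load_cohort"]

IMPORTANCE_MODELS = ("terminal_ends", "hubs", "uniform")

# terminal layers are this fraction of a drawn middle-layer width (min 3)
_TERMINAL_WIDTH = 0.5
# degree multiplier applied to edge probabilities at hub nodes
_HUB_BOOST = 3.0
# middle-layer planting rate under terminal_ends is importance_rate / 4
_MIDDLE_DILUTION = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic pathway cohort."""

    n_pathways: int = 150
    layers: int = 5
    nodes_per_layer: tuple[int, int] = (6, 12)
    p_forward: float = 0.22
    p_terminal: float = 0.75
    p_skip: float = 0.03
    p_feedback: float = 0.0
    hub_fraction: float = 0.1
    importance_model: str = "terminal_ends"
    importance_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 3:
            raise ValueError("layers must be >= 3 (upstream, middle, downstream)")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        lo, hi = self.nodes_per_layer
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid nodes_per_layer range {self.nodes_per_layer}")
        for name in ("p_forward", "p_terminal", "p_skip", "p_feedback",
                     "hub_fraction", "importance_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.importance_model not in IMPORTANCE_MODELS:
            raise ValueError(
                f"importance_model must be one of {IMPORTANCE_MODELS}"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    graphs: tuple[PathwayGraph, ...]
    important: GeneSet
    spec: SyntheticSpec
    hubs: frozenset[str] = field(default_factory=frozenset)


def _layer_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    lo, hi = spec.nodes_per_layer
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.layers)]
    for t in (0, spec.layers - 1):
        sizes[t] = max(3, round(sizes[t] * _TERMINAL_WIDTH))
    return sizes


def _generate_pathway(
    spec: SyntheticSpec, index: int
) -> tuple[PathwayGraph, list[str], list[str]]:
    """Return (graph, important node ids, hub node ids) for one pathway."""
    rng = np.random.default_rng(spec.seed + index)
    sizes = _layer_sizes(spec, rng)
    layers = [
        [f"p{index}_l{j}_n{i}" for i in range(sizes[j])]
        for j in range(spec.layers)
    ]
    nodes = [v for layer in layers for v in layer]
    n_hubs = int(np.ceil(spec.hub_fraction * len(nodes)))
    hubs = set(rng.choice(nodes, size=n_hubs, replace=False)) if n_hubs else set()

    def edge_prob(u: str, v: str, base: float) -> float:
        boost = _HUB_BOOST if (u in hubs or v in hubs) else 1.0
        return min(1.0, base * boost)

    edges: set[tuple[str, str]] = set()
    last = spec.layers - 1
    for j in range(last):
        # adjacent-layer edges; terminal fan-out/fan-in is dense
        base = spec.p_terminal if (j == 0 or j + 1 == last) else spec.p_forward
        for u in layers[j]:
            for v in layers[j + 1]:
                if rng.random() < edge_prob(u, v, base):
                    edges.add((u, v))
        # forward skip edges to any deeper layer
        for k in range(j + 2, spec.layers):
            for u in layers[j]:
                for v in layers[k]:
                    if rng.random() < edge_prob(u, v, spec.p_skip):
                        edges.add((u, v))
    # guarantee every non-terminal node feeds forward and every
    # non-initial node is fed, so no isolated pass-through nodes arise
    for j in range(last):
        for u in layers[j]:
            if not any(e[0] == u for e in edges):
                edges.add((u, layers[j + 1][int(rng.integers(sizes[j + 1]))]))
    for j in range(1, spec.layers):
        for v in layers[j]:
            if not any(e[1] == v for e in edges):
                edges.add((layers[j - 1][int(rng.integers(sizes[j - 1]))], v))
    if spec.p_feedback > 0:
        for j in range(1, spec.layers):
            for u in layers[j]:
                for k in range(j):
                    for v in layers[k]:
                        if rng.random() < spec.p_feedback:
                            edges.add((u, v))

    important: list[str] = []
    if spec.importance_model == "uniform":
        for v in nodes:
            if rng.random() < spec.importance_rate:
                important.append(v)
    elif spec.importance_model == "terminal_ends":
        terminal = set(layers[0]) | set(layers[last])
        for v in nodes:
            rate = (
                spec.importance_rate
                if v in terminal
                else spec.importance_rate / _MIDDLE_DILUTION
            )
            if rng.random() < rate:
                important.append(v)
    else:  # hubs
        for v in nodes:
            rate = (
                spec.importance_rate
                if v in hubs
                else spec.importance_rate / _MIDDLE_DILUTION
            )
            if rng.random() < rate:
                important.append(v)

    ordered_edges = sorted(edges)
    graph = from_edge_list(ordered_edges, pathway_id=f"synthetic_p{index}", nodes=nodes)
    return graph, important, sorted(hubs)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a deterministic cohort of layered pathway graphs."""
    graphs: list[PathwayGraph] = []
    important: set[str] = set()
    hubs: set[str] = set()
    for index in range(spec.n_pathways):
        g, imp, hb = _generate_pathway(spec, index)
        graphs.append(g)
        important.update(imp)
        hubs.update(hb)
    if not important:
        # degenerate spec (rate 0); keep the cohort contract of a non-empty set
        important.add(graphs[0].nodes[0])
    return SyntheticCohort(
        graphs=tuple(graphs),
        important=GeneSet("synthetic_important", frozenset(important)),
        spec=spec,
        hubs=frozenset(hubs),
    )


def expected_signal(spec: SyntheticSpec) -> dict[tuple[str, str], str]:
    """Qualitative slope contract per (model, variant) under this spec.

    Values are ``"positive"`` (the importance-fraction regression slope
    should be positive) or ``"flat"`` (no planted linear signal).  Only the
    pairs whose behaviour the construction warrants are listed.
    """
    if spec.importance_model == "uniform":
        return {
            ("pagerank", "ssc"): "flat",
            ("pagerank", "undirected"): "flat",
            ("katz", "ssc"): "flat",
            ("katz", "source"): "flat",
            ("katz", "sink"): "flat",
            ("degree", "undirected"): "flat",
        }
    if spec.importance_model == "terminal_ends":
        return {
            ("pagerank", "ssc"): "positive",
            ("pagerank", "undirected"): "positive",
            ("katz", "ssc"): "positive",
            ("katz", "source"): "flat",
            ("katz", "sink"): "flat",
            ("degree", "undirected"): "positive",
        }
    return {  # hubs
        ("degree", "undirected"): "positive",
        ("pagerank", "undirected"): "positive",
        ("katz", "ssc"): "positive",
    }


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write edge-list TSVs, an importance GMT and a JSON spec sidecar."""
    os.makedirs(directory, exist_ok=True)
    for g in cohort.graphs:
        path = os.path.join(directory, f"{g.pathway_id}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# source\ttarget\n")
            for u, v in g.edges:
                fh.write(f"{u}\t{v}\n")
    write_gene_sets_gmt(
        [cohort.important], os.path.join(directory, "important.gmt")
    )
    sidecar = asdict(cohort.spec)
    with open(os.path.join(directory, "spec.json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_cohort(directory) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    with open(os.path.join(directory, "spec.json"), encoding="utf-8") as fh:
        spec = SyntheticSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.load(fh).items()
        })
    graphs = []
    for name in sorted(os.listdir(directory)):
        if name.endswith(".tsv"):
            graphs.append(read_edge_list(os.path.join(directory, name)))
    important = read_gene_set(os.path.join(directory, "important.gmt"), "gmt")[0]
    return SyntheticCohort(tuple(graphs), important, spec)
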