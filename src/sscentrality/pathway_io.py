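"""Reading KGML pathways and gene sets; pathway quality filtering.

KGML (KEGG Markup Language) encodes a pathway as ``entry`` elements —
genes, compounds, maps, or groups of entries — connected by ``relation``
elements.  Only gene entries become graph nodes here: an entry whose
``name`` attribute lists several gene identifiers is fanned out into one
node per identifier, group entries are expanded to their gene components,
and every relation is expanded over the gene identifiers of its two
endpoint entries.  ``map``/``compound`` entries and ``maplink`` relations
are skipped.

Quality filters mirror a standard pre-processing of KEGG pathway
collections: drop pathways that are very large (>1000 nodes and >4000
edges), trivially small (<=20 nodes or <=20 edges), spectrally extreme
(largest adjacency eigenvalue above 10, which would force a tiny Katz
alpha), degenerate (some configured centrality is constant), or carry too
few a-priori important genes (<=5) for stable testing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from lxml import etree

from .centrality import DEFAULT_MODEL_SET, DEFAULT_PARAMS, ConvergenceError, compute_centrality
from .graph import PathwayGraph, from_edge_list, spectral_radius

__all__ = [
    "GeneSet",
    "FilterReport",
    "FilterConfig",
    "read_kgml",
    "read_gene_set",
    "write_gene_sets_gmt",
    "filter_pathways",
    "filter_report_frame",
]

logger = logging.getLogger(__name__)

FILTER_REASONS = (
    "too_large",
    "too_small",
    "eigenvalue",
    "constant_centrality",
    "too_few_important",
    "none",
)


@dataclass(frozen=True)
class GeneSet:
    """A named set of a-priori important gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.genes | other.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of the quality filters for one pathway.

    ``reason`` is the first failing rule in the fixed evaluation order, or
    ``"none"`` for kept pathways.
    """

    pathway_id: str
    decision: str  # kept | excluded
    reason: str
    n_nodes: int
    n_edges: int
    lambda_1: float
    n_important: int


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the pathway quality filters."""

    max_nodes: int = 1000
    max_edges: int = 4000
    min_nodes: int = 20  # exclusive: <= min_nodes is excluded
    min_edges: int = 20
    max_eigenvalue: float = 10.0
    min_important: int = 5  # exclusive: <= min_important is excluded
    models: tuple[tuple[str, str], ...] = DEFAULT_MODEL_SET


def read_kgml(path) -> PathwayGraph:
    """Parse a KGML file into a directed :class:`PathwayGraph`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed KGML ({exc})") from exc
    root = tree.getroot()
    pathway_id = root.get("name") or os.path.splitext(os.path.basename(str(path)))[0]

    entry_genes: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    node_order: list[str] = []
    seen: set[str] = set()
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            genes = (entry.get("name") or "").split()
            entry_genes[eid] = genes
            for gid in genes:
                if gid not in seen:
                    seen.add(gid)
                    node_order.append(gid)
        elif etype == "group":
            groups[eid] = [
                c.get("id") for c in entry.findall("component") if c.get("id")
            ]
        # map / compound / ortholog entries are not graph nodes

    def resolve(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in groups:
            out: list[str] = []
            for member in groups[eid]:
                out.extend(resolve(member))
            return out
        return []

    rows: list[tuple[str, str]] = []
    for rel in root.findall("relation"):
        if rel.get("type") == "maplink":
            continue
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        known = set(entry_genes) | set(groups)
        if e1 not in known or e2 not in known:
            logger.warning(
                "%s: relation (%s -> %s) references unknown entry; skipped",
                pathway_id, e1, e2,
            )
            continue
        for u in resolve(e1):
            for v in resolve(e2):
                rows.append((u, v))

    return from_edge_list(rows, pathway_id=pathway_id, nodes=node_order)


def _normalize(gene: str) -> str:
    return gene.strip()


def read_gene_set(path, format: str = "gmt") -> list[GeneSet]:
    """Read gene sets from GMT (one set per row) or a gene-per-line list."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        if format == "gmt":
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{i + 1}: GMT rows need name, description and "
                        "at least one member"
                    )
                name, _desc, *members = parts
                genes = frozenset(_normalize(m) for m in members if m.strip())
                if not genes:
                    raise ValueError(f"{path}:{i + 1}: gene set {name!r} is empty")
                sets.append(GeneSet(name, genes))
        elif format == "list":
            genes = frozenset(
                _normalize(line) for line in fh if line.strip()
            )
            name = os.path.splitext(os.path.basename(str(path)))[0]
            if not genes:
                raise ValueError(f"{path}: empty gene list")
            sets.append(GeneSet(name, genes))
        else:
            raise ValueError(f"unknown gene set format {format!r}")
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gene_sets_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


def _has_constant_profile(g: PathwayGraph, config: FilterConfig) -> bool:
    for model, variant in config.models:
        try:
            profile = compute_centrality(g, model, variant, DEFAULT_PARAMS[model])
        except ConvergenceError:
            # inadmissible parameters on this graph: the eigenvalue rule
            # upstream is responsible; not a constant-centrality failure
            continue
        if profile.is_constant():
            return True
    return False


def filter_pathways(
    graphs: Sequence[PathwayGraph],
    important: GeneSet,
    config: FilterConfig | None = None,
) -> tuple[list[PathwayGraph], list[FilterReport]]:
    """Apply the quality filters in fixed order; report every decision.

    Order: (1) too large, (2) too small, (3) eigenvalue, (4) constant
    centrality under any configured model, (5) too few important genes.
    ``kept + excluded`` partitions the input.
    """
    config = config or FilterConfig()
    kept: list[PathwayGraph] = []
    reports: list[FilterReport] = []
    for g in graphs:
        n, m = g.n_nodes, g.n_edges
        lam = spectral_radius(g) if n else 0.0
        n_imp = sum(1 for v in g.nodes if v in important)
        reason = "none"
        if n > config.max_nodes and m > config.max_edges:
            reason = "too_large"
        elif n <= config.min_nodes or m <= config.min_edges:
            reason = "too_small"
        elif lam > config.max_eigenvalue:
            reason = "eigenvalue"
        elif _has_constant_profile(g, config):
            reason = "constant_centrality"
        elif n_imp <= config.min_important:
            reason = "too_few_important"
        decision = "kept" if reason == "none" else "excluded"
        if decision == "kept":
            kept.append(g)
        reports.append(
            FilterReport(g.pathway_id, decision, reason, n, m, lam, n_imp)
        )
    return kept, reports


def filter_report_frame(reports: Sequence[FilterReport]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "decision": r.decision,
                "reason": r.reason,
                "n_nodes": r.n_nodes,
                "n_edges": r.n_edges,
                "lambda_1": r.lambda_1,
                "n_important": r.n_important,
            }
            for r in reports
        ]
    )
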