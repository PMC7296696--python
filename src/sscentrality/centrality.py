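"""Source, Sink and Source/Sink (SSC) centrality models.

Every spectral model here is a fixed point of a linear recurrence
``C = beta + M C`` with a model-specific non-negative operator ``M``:

====================  =================================
model / variant       operator M
====================  =================================
PageRank sink         alpha * A^T D_out^{-1}
PageRank source       alpha * A   D_in^{-1}
Katz source           alpha * A
Katz sink             alpha * A^T
Laplacian source      alpha * D_out^{-1} A
Laplacian sink        alpha * D_in^{-1}  A^T
====================  =================================

with ``D_out``/``D_in`` the diagonal out-/in-degree matrices clamped at 1.
The *source* variant scores a node as a sender of signal, the *sink* variant
as a receiver (the same model on the transposed graph), and the *ssc* variant
is their elementwise sum computed with identical (alpha, beta).

Note: this PageRank is the literal closed form ``(I - alpha A^T D^{-1})^{-1}
beta`` with a constant restart vector beta.  There is no dangling-node mass
redistribution and no sum-to-one renormalization, so raw scores differ from
textbook (stochastic-matrix) PageRank even though the ranking logic is the
same.

Degree and closeness centrality are non-spectral and take no parameters.
Closeness follows the harmonic convention: unreachable pairs contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph import PathwayGraph, spectral_radius, transpose, underlying_undirected

__all__ = [
    "CentralityParams",
    "CentralityProfile",
    "ConvergenceError",
    "MODELS",
    "VARIANTS",
    "DEFAULT_PARAMS",
    "DEFAULT_MODEL_SET",
    "degree_centrality",
    "pagerank_centrality",
    "katz_centrality",
    "laplacian_centrality",
    "closeness_centrality",
    "compute_centrality",
    "solve_spectral",
    "profiles_to_frame",
]

MODELS = ("degree", "pagerank", "katz", "laplacian", "closeness")
VARIANTS = ("source", "sink", "ssc", "undirected")

# Katz is refused within this relative margin of the convergence radius
_KATZ_MARGIN = 0.999


class ConvergenceError(ValueError):
    """A spectral solve was refused or failed to converge."""


@dataclass(frozen=True)
class CentralityParams:
    """Dampening factor ``alpha`` and restart/offset constant ``beta``.

    ``beta`` is a scalar broadcast to a constant vector of length n.  Both
    must be positive; model-specific admissibility (``alpha < 1`` for
    PageRank/Laplacian, ``alpha < 1/lambda_1`` for Katz) is checked at solve
    time.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


#: Published default parameters per model.
DEFAULT_PARAMS: dict[str, CentralityParams | None] = {
    "degree": None,
    "pagerank": CentralityParams(alpha=0.85, beta=0.15),
    "katz": CentralityParams(alpha=0.1, beta=1.0),
    "laplacian": CentralityParams(alpha=0.85, beta=1.0),
    "closeness": None,
}

#: The twelve (model, variant) pairs analysed by default: degree, the four
#: PageRank variants, Source/Sink/SSC Katz and Laplacian, and SSC closeness.
DEFAULT_MODEL_SET: tuple[tuple[str, str], ...] = (
    ("degree", "undirected"),
    ("pagerank", "source"),
    ("pagerank", "sink"),
    ("pagerank", "ssc"),
    ("pagerank", "undirected"),
    ("katz", "source"),
    ("katz", "sink"),
    ("katz", "ssc"),
    ("laplacian", "source"),
    ("laplacian", "sink"),
    ("laplacian", "ssc"),
    ("closeness", "ssc"),
)


@dataclass(frozen=True)
class CentralityProfile:
    """Per-node centrality scores for one (pathway, model, variant) triple."""

    pathway_id: str
    model: str
    variant: str
    params: CentralityParams | None
    nodes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.nodes),):
            raise ValueError("scores length must equal node count")
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"{self.pathway_id}: non-finite centrality scores")

    def is_constant(self, rtol: float = 1e-12) -> bool:
        if len(self.scores) <= 1:
            return True
        span = float(np.ptp(self.scores))
        scale = max(1.0, float(np.max(np.abs(self.scores))))
        return span <= rtol * scale


def solve_spectral(
    M: np.ndarray,
    beta: np.ndarray,
    method: str = "closed_form",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Solve ``C = beta + M C`` for a contraction operator ``M``.

    ``closed_form`` solves ``(I - M) C = beta`` directly; ``iterative``
    applies the fixed-point recurrence starting at ``beta`` until the
    max-norm change drops below ``tol``.
    """
    beta = np.asarray(beta, dtype=float)
    if method == "closed_form":
        n = M.shape[0]
        try:
            return np.linalg.solve(np.eye(n) - M, beta)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular spectral system: {exc}") from exc
    if method == "iterative":
        x = beta.copy()
        for _ in range(max_iter):
            x_next = beta + M @ x
            if float(np.max(np.abs(x_next - x))) < tol:
                return x_next
            x = x_next
        residual = float(np.max(np.abs(beta + M @ x - x)))
        raise ConvergenceError(
            f"fixed-point iteration did not converge in {max_iter} steps "
            f"(last max-norm residual {residual:.3e})"
        )
    raise ValueError(f"unknown method {method!r}")


def _operator(g: PathwayGraph, model: str, variant: str, alpha: float) -> np.ndarray:
    b = g.bundle()
    if model == "pagerank":
        if variant == "sink":
            return alpha * (b.A.T / b.d_out)
        if variant == "source":
            return alpha * (b.A / b.d_in)
    elif model == "katz":
        if variant == "source":
            return alpha * b.A
        if variant == "sink":
            return alpha * b.A.T
    elif model == "laplacian":
        if variant == "source":
            return alpha * (b.A / b.d_out[:, None])
        if variant == "sink":
            return alpha * (b.A.T / b.d_in[:, None])
    raise ValueError(f"no operator for model={model!r} variant={variant!r}")


def _check_params(g: PathwayGraph, model: str, params: CentralityParams) -> None:
    if model in ("pagerank", "laplacian"):
        if not params.alpha < 1:
            raise ValueError(
                f"{model} requires alpha in (0, 1), got {params.alpha}"
            )
    elif model == "katz":
        lam = spectral_radius(g)
        if lam > 0 and params.alpha >= _KATZ_MARGIN / lam:
            raise ConvergenceError(
                f"{g.pathway_id}: Katz alpha={params.alpha} violates the "
                f"convergence condition alpha < 1/lambda_1 = {1.0 / lam:.6g} "
                f"(largest eigenvalue {lam:.6g})"
            )


def _spectral_profile(
    g: PathwayGraph,
    model: str,
    variant: str,
    params: CentralityParams,
    method: str,
    tol: float,
) -> np.ndarray:
    beta_vec = np.full(g.n_nodes, params.beta)
    M = _operator(g, model, variant, params.alpha)
    return solve_spectral(M, beta_vec, method=method, tol=tol)


def degree_centrality(g: PathwayGraph) -> CentralityProfile:
    """Sum of in-degree and out-degree per node (unclamped)."""
    A = g.adjacency()
    scores = A.sum(axis=1) + A.sum(axis=0)
    return CentralityProfile(g.pathway_id, "degree", "undirected", None, g.nodes, scores)


def _source_sink_model(
    g: PathwayGraph,
    model: str,
    variant: str,
    params: CentralityParams,
    method: str,
    tol: float,
    undirected_ok: bool,
) -> CentralityProfile:
    if variant == "ssc":
        so = _spectral_profile(g, model, "source", params, method, tol)
        si = _spectral_profile(g, model, "sink", params, method, tol)
        scores = so + si
    elif variant in ("source", "sink"):
        scores = _spectral_profile(g, model, variant, params, method, tol)
    elif variant == "undirected" and undirected_ok:
        scores = _spectral_profile(
            underlying_undirected(g), model, "sink", params, method, tol
        )
    else:
        raise ValueError(f"{model} does not offer variant {variant!r}")
    return CentralityProfile(g.pathway_id, model, variant, params, g.nodes, scores)


def pagerank_centrality(
    g: PathwayGraph,
    variant: str = "ssc",
    params: CentralityParams | None = None,
    method: str = "closed_form",
    tol: float = 1e-12,
) -> CentralityProfile:
    """PageRank-family centrality.

    Sink is the standard PageRank of the directed graph (receivers score
    high); source is PageRank on the transposed graph; ssc their sum;
    undirected runs on the symmetrized graph, where source and sink
    coincide.
    """
    params = params or DEFAULT_PARAMS["pagerank"]
    _check_params(g, "pagerank", params)
    return _source_sink_model(g, "pagerank", variant, params, method, tol, True)


def katz_centrality(
    g: PathwayGraph,
    variant: str = "ssc",
    params: CentralityParams | None = None,
    method: str = "closed_form",
    tol: float = 1e-12,
) -> CentralityProfile:
    """Katz-family centrality; source is standard directed Katz.

    Refused unless ``alpha < 1/lambda_1`` with a small safety margin; no
    undirected variant is offered (symmetrization inflates ``lambda_1`` and
    would force a tiny global alpha).
    """
    params = params or DEFAULT_PARAMS["katz"]
    if variant == "undirected":
        raise ValueError("katz does not offer an undirected variant")
    _check_params(g, "katz", params)
    return _source_sink_model(g, "katz", variant, params, method, tol, False)


def laplacian_centrality(
    g: PathwayGraph,
    variant: str = "ssc",
    params: CentralityParams | None = None,
    method: str = "closed_form",
    tol: float = 1e-12,
) -> CentralityProfile:
    """Degree-averaged spectral centrality (influence-matrix model).

    The source variant solves ``C = (I - alpha D_out^{-1} A)^{-1} beta``,
    i.e. a node's score follows the average score of its out-neighbors; it
    equals the geometric series of the normalized influence operator applied
    to beta.  No undirected variant (constant on connected components).
    """
    params = params or DEFAULT_PARAMS["laplacian"]
    if variant == "undirected":
        raise ValueError("laplacian does not offer an undirected variant")
    _check_params(g, "laplacian", params)
    return _source_sink_model(g, "laplacian", variant, params, method, tol, False)


def _harmonic_out(g: PathwayGraph) -> np.ndarray:
    A = csr_matrix(g.adjacency())
    d = shortest_path(A, method="D", directed=True, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1)


def closeness_centrality(g: PathwayGraph, variant: str = "ssc") -> CentralityProfile:
    """Harmonic closeness: sum of reciprocal shortest-path distances.

    Source uses distances *from* the node, sink distances *to* it;
    unreachable pairs contribute 0 and d(v, v) is excluded.
    """
    if variant == "source":
        scores = _harmonic_out(g)
    elif variant == "sink":
        scores = _harmonic_out(transpose(g))
    elif variant == "ssc":
        scores = _harmonic_out(g) + _harmonic_out(transpose(g))
    elif variant == "undirected":
        scores = _harmonic_out(underlying_undirected(g))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return CentralityProfile(g.pathway_id, "closeness", variant, None, g.nodes, scores)


def compute_centrality(
    g: PathwayGraph,
    model: str,
    variant: str,
    params: CentralityParams | None = None,
    method: str = "closed_form",
    tol: float = 1e-12,
) -> CentralityProfile:
    """Dispatch to the requested centrality model."""
    if model == "degree":
        return degree_centrality(g)
    if model == "closeness":
        return closeness_centrality(g, variant)
    if model == "pagerank":
        return pagerank_centrality(g, variant, params, method, tol)
    if model == "katz":
        return katz_centrality(g, variant, params, method, tol)
    if model == "laplacian":
        return laplacian_centrality(g, variant, params, method, tol)
    raise ValueError(f"unknown model {model!r}")


def with_alpha(params: CentralityParams, alpha: float) -> CentralityParams:
    return replace(params, alpha=alpha)


def profiles_to_frame(profiles) -> "pandas.DataFrame":  # noqa: F821
    """Serialize profiles to a tidy table (full float precision on write)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for node, score in zip(p.nodes, p.scores):
            rows.append(
                {
                    "pathway_id": p.pathway_id,
                    "node_id": node,
                    "model": p.model,
                    "variant": p.variant,
                    "alpha": p.params.alpha if p.params else np.nan,
                    "beta": p.params.beta if p.params else np.nan,
                    "score": float(score),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pathway_id", "node_id", "model", "variant", "alpha", "beta", "score"],
    )
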