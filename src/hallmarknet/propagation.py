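"""Network propagation of hallmark–disease scores by random walk with restart.

Literature-derived scores F0 are superimposed on the disease nodes of a
multimorbidity network and smoothed by iterating

    F_i = alpha * W' F_{i-1} + (1 - alpha) * F0

where W' is the row-normalised weighted adjacency matrix, w'(r,c) =
w(r,c)/d(r).  The restart weight alpha (default 0.5) balances network
structure against the prior.  The stationary point is the linear system
(I - alpha W') F = (1 - alpha) F0, which the iteration approaches
geometrically whenever the spectral radius of alpha W' is below 1.

Propagation amplifies regions of the network where many neighbours
share a high prior — "guilt by association" — so a disease with little
direct literature support can be promoted into the top ranks if its
multimorbidity neighbours are strongly hallmark-associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import MorbidityNetwork, top_k_nodes

__all__ = [
    "NormalizedAdjacency",
    "PropagationState",
    "normalize_adjacency",
    "propagate",
    "rerank_posterior",
    "newly_prioritized",
]


@dataclass
class NormalizedAdjacency:
    """Row-normalised adjacency W' over a fixed node order.

    ``mode="degree"`` divides each row by the node's edge count (the
    literal reading of "degree" for a weighted network); with
    ``mode="strength"`` rows are divided by the weighted degree, so
    every non-isolated row sums to 1.  Isolated nodes get zero rows.
    """

    node_order: list[str]
    matrix: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        n = len(self.node_order)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match node order")
        if (self.matrix < 0).any():
            raise ValueError("negative entries in normalised adjacency")
        if np.diag(self.matrix).any():
            raise ValueError("nonzero diagonal in normalised adjacency")
        if self.mode == "strength":
            sums = self.matrix.sum(axis=1)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1.0):
                raise ValueError("strength mode rows must sum to 1")


@dataclass
class PropagationState:
    """Final iterate and convergence diagnostics of one propagation run."""

    node_order: list[str]
    prior: np.ndarray
    posterior: np.ndarray
    alpha: float
    n_iter: int
    converged: bool
    deltas: list[float] = field(default_factory=list)

    def posterior_scores(self) -> dict[str, float]:
        return {n: float(s) for n, s in zip(self.node_order, self.posterior)}


def normalize_adjacency(network: MorbidityNetwork, mode: str = "degree") -> NormalizedAdjacency:
    """Build W' with w'(r,c) = w(r,c)/d(r) for adjacent pairs, 0 otherwise."""
    if mode not in ("degree", "strength"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    nodes = network.nodes
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, data in network.graph.edges(data=True):
        w[index[u], index[v]] = data["weight"]
        w[index[v], index[u]] = data["weight"]
    if mode == "degree":
        d = (w > 0).sum(axis=1).astype(float)
    else:
        d = w.sum(axis=1)
    out = np.divide(w, d[:, None], out=np.zeros_like(w), where=d[:, None] > 0)
    return NormalizedAdjacency(node_order=nodes, matrix=out, mode=mode)


def propagate(
    w_prime: NormalizedAdjacency,
    prior: Mapping[str, float] | np.ndarray,
    alpha: float = 0.5,
    max_iter: int = 30,
    tol: float | None = 1e-9,
) -> PropagationState:
    """Iterate F_i = alpha W' F_{i-1} + (1-alpha) F0.

    Runs *max_iter* iterations (30 by default) with an optional early
    stop when the max-abs change drops below *tol*; pass ``tol=None``
    for a fixed iteration count.  The prior may be a mapping from node
    id to score (missing nodes default to 0) or a vector aligned with
    ``w_prime.node_order``.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    nodes = w_prime.node_order
    if isinstance(prior, Mapping):
        unknown = set(prior) - set(nodes)
        if unknown:
            raise ValueError(f"prior has unknown nodes: {sorted(unknown)[:5]}")
        f0 = np.array([float(prior.get(n, 0.0)) for n in nodes])
    else:
        f0 = np.asarray(prior, dtype=float)
        if f0.shape != (len(nodes),):
            raise ValueError("prior vector length does not match node order")
    f = f0.copy()
    deltas: list[float] = []
    converged = False
    i = 0
    for i in range(1, max_iter + 1):
        f_next = alpha * (w_prime.matrix @ f) + (1 - alpha) * f0
        delta = float(np.max(np.abs(f_next - f)))
        deltas.append(delta)
        f = f_next
        if tol is not None and delta < tol:
            converged = True
            break
    return PropagationState(
        node_order=list(nodes),
        prior=f0,
        posterior=f,
        alpha=alpha,
        n_iter=i,
        converged=converged,
        deltas=deltas,
    )


def rerank_posterior(state: PropagationState, k: int = 30) -> list[str]:
    """Top-k nodes by posterior score, deterministic lexicographic tie-break.

    The selected set can be fed back to the permutation density test to
    assess the significance of the propagated subnetwork.  If *k*
    exceeds the node count all nodes are returned.
    """
    k = min(k, len(state.node_order))
    return top_k_nodes(state.posterior_scores(), k)


def newly_prioritized(
    pre: Sequence[str],
    post: Sequence[str],
    flags: Mapping[str, bool],
) -> list[str]:
    """Diseases entering the top list only after propagation, filtered to flagged ones.

    *flags* marks diseases with incompletely understood pathogenesis or
    pathophysiology (an editorial input).  The result preserves
    posterior rank order.
    """
    pre_set = set(pre)
    return [d for d in post if d not in pre_set and flags.get(d, False)]
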