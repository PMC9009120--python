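"""Age-stratified multimorbidity networks, subnetwork density, permutation null.

Nodes are age-related diseases; an undirected edge joins two diseases
whose diagnoses co-occur in patients with a positive, significant
partial correlation (the correlation is the edge weight).  For a node
set S the subnetwork density is

    D = 2 E_s / (V_s (V_s - 1))

with E_s the number of edges internal to S — a topology-only statistic,
independent of edge weights.

Significance of the density of a score-selected top-k subnetwork is
assessed by a label-shuffle null: the score vector is permuted over all
network nodes, the new top-k set's density D_k recomputed, and

    p = #{k : D_k >= D_0} / K

over K shuffles.  p-values are corrected per hallmark across age strata
with Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MorbidityNetwork",
    "PermutationResult",
    "load_network",
    "subnetwork_density",
    "top_k_nodes",
    "permutation_density_test",
    "bh_adjust",
    "significance_stars",
]


class NetworkValidationError(ValueError):
    """Raised for invalid edge lists (non-positive weights, conflicting duplicates)."""


@dataclass
class MorbidityNetwork:
    """Undirected, positively weighted disease network for one age stratum."""

    graph: nx.Graph
    stratum: str

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise NetworkValidationError(f"self-loop at node {u!r}")
            w = data.get("weight")
            if w is None or w <= 0:
                raise NetworkValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class PermutationResult:
    """Observed density, null draws, and the empirical permutation p-value."""

    observed: float
    null: np.ndarray
    n_permutations: int
    p_value: float
    seed: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")


def load_network(path: str | Path, stratum: str | None = None) -> MorbidityNetwork:
    """Load one stratum's network from a tab-delimited edge list.

    Columns (header row): ``source``, ``target``, ``weight``,
    ``stratum``.  Rows from other strata are ignored when *stratum* is
    given; with ``stratum=None`` the file must contain a single stratum.
    Duplicate undirected edges merge only if their weights agree exactly.
    """
    graph = nx.Graph()
    seen_strata: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "weight"]:
            raise NetworkValidationError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            src, dst, weight_s = fields[0], fields[1], fields[2]
            row_stratum = fields[3] if len(fields) > 3 else ""
            seen_strata.add(row_stratum)
            if stratum is not None and row_stratum != stratum:
                continue
            try:
                weight = float(weight_s)
            except ValueError as exc:
                raise NetworkValidationError(f"{path}:{lineno}: bad weight {weight_s!r}") from exc
            if weight <= 0:
                raise NetworkValidationError(
                    f"{path}:{lineno}: non-positive weight {weight} on edge ({src}, {dst})"
                )
            if src == dst:
                raise NetworkValidationError(f"{path}:{lineno}: self-loop at {src!r}")
            if graph.has_edge(src, dst):
                existing = graph.edges[src, dst]["weight"]
                if existing != weight:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: duplicate edge ({src}, {dst}) with conflicting "
                        f"weights {existing} and {weight}"
                    )
                continue
            graph.add_edge(src, dst, weight=weight)
    if stratum is None:
        if len(seen_strata) > 1:
            raise NetworkValidationError(
                f"{path}: multiple strata {sorted(seen_strata)}; pass stratum="
            )
        stratum = next(iter(seen_strata)) if seen_strata else ""
    return MorbidityNetwork(graph=graph, stratum=stratum)


def subnetwork_density(network: MorbidityNetwork, nodes: Iterable[str]) -> float:
    """Density 2E_s/(V_s(V_s-1)) of the subgraph induced by *nodes*."""
    node_set = set(nodes)
    missing = node_set - set(network.graph.nodes)
    if missing:
        raise ValueError(f"nodes not in network: {sorted(missing)}")
    v = len(node_set)
    if v < 2:
        raise ValueError("subnetwork density undefined for fewer than 2 nodes")
    e = network.graph.subgraph(node_set).number_of_edges()
    return 2.0 * e / (v * (v - 1))


def top_k_nodes(scores: Mapping[str, float], k: int) -> list[str]:
    """Top-k node ids by score, descending, lexicographic tie-break."""
    ranked = sorted(scores, key=lambda n: (-scores[n], n))
    return ranked[:k]


def permutation_density_test(
    network: MorbidityNetwork,
    scores: Mapping[str, float],
    k: int = 30,
    n_permutations: int = 20000,
    seed: int = 0,
    smoothed: bool = False,
) -> PermutationResult:
    """Label-shuffle permutation test for top-k subnetwork density.

    The observed statistic D_0 is the density of the top-k nodes by
    score.  Each of *n_permutations* shuffles permutes the score vector
    uniformly over all network nodes (zero-scored nodes included), takes
    the new top-k with the same deterministic tie-break, and records its
    density.  ``p = #{D_k >= D_0} / K`` as printed; ``smoothed=True``
    applies add-one smoothing (sum+1)/(K+1) so p can never be exactly 0.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    nodes = network.nodes  # sorted: lexicographic order doubles as the tie-break
    missing = set(nodes) - set(scores)
    if missing:
        raise ValueError(f"scores missing for nodes: {sorted(missing)[:5]}")
    if k > len(nodes):
        raise ValueError(f"k={k} exceeds node count {len(nodes)}")
    index = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in network.graph.edges:
        adj[index[u], index[v]] = True
        adj[index[v], index[u]] = True
    score_vec = np.array([float(scores[n]) for n in nodes])

    def density_of(order: np.ndarray) -> float:
        top = order[:k]
        e = adj[np.ix_(top, top)].sum() // 2
        return 2.0 * e / (k * (k - 1))

    # stable argsort on -scores: equal scores keep ascending (lexicographic) node order
    observed = density_of(np.argsort(-score_vec, kind="stable"))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = density_of(np.argsort(-rng.permutation(score_vec), kind="stable"))
    exceed = int((null >= observed - 1e-12).sum())
    if smoothed:
        p = (exceed + 1) / (n_permutations + 1)
    else:
        p = exceed / n_permutations
    return PermutationResult(
        observed=observed, null=null, n_permutations=n_permutations, p_value=p, seed=seed
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values for one test family.

    The conventional family is the four age strata of one hallmark, but
    any grouping may be passed.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def significance_stars(p: float) -> str:
    """Conventional star annotation for an (adjusted) p-value."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return ""
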