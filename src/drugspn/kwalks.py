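"""Lateral movement: bounded K-walk relevance and subnetwork extraction.

Walks start at one seed and are absorbed at the remaining seeds; within a
step bound ``L_max`` the expected number of passages over each directed edge
and visits to each node follow from the transient-state occupancies of the
absorbing Markov chain:

    alpha_0 = e_start
    alpha_{t+1}(j) = sum_{i transient} alpha_t(i) T(i, j)   (j transient)
    visits(i)      = sum_{t < L_max} alpha_t(i)
    passage(i->j)  = visits(i) * T(i, j)

Per-start tables are averaged over every seed taken in turn as the start, so
relevance is on a per-walk scale and symmetric in seed ordering.  The relevant
subnetwork keeps the edges above an automatically chosen relevance threshold:
candidate thresholds are the distinct undirected edge relevances scanned in
descending order, and the largest threshold maximizing the number of connected
seed pairs wins (ties go to fewer retained edges).  The retained graph is
restricted to components containing at least one seed; seeds never connect to
anything are returned as singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import networkx as nx
import numpy as np

from .rwr import TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AbsorbingChainSpec",
    "EdgeRelevanceTable",
    "bounded_expected_passages",
    "aggregate_relevance",
    "extract_subnetwork",
]

DEFAULT_L_MAX = 50


@dataclass(frozen=True)
class AbsorbingChainSpec:
    """One bounded walk: a start seed, the absorbing remainder, a step cap."""

    T: TransitionMatrix
    start: str
    absorbing: frozenset[str]
    l_max: int = DEFAULT_L_MAX

    def __post_init__(self):
        if not self.absorbing:
            raise ValueError("absorbing set must be non-empty")
        if self.start in self.absorbing:
            raise ValueError(f"start node {self.start!r} cannot be absorbing")
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")
        missing = ({self.start} | set(self.absorbing)) - set(self.T.index)
        if missing:
            raise ValueError(f"nodes not in network: {sorted(missing)}")


@dataclass
class EdgeRelevanceTable:
    """Expected passages per directed edge and visits per node."""

    nodes: list[str]
    passages: dict[tuple[str, str], float]
    visits: dict[str, float]

    def undirected(self) -> dict[tuple[str, str], float]:
        """Relevance per undirected edge: sum of both directions."""
        out: dict[tuple[str, str], float] = {}
        for (u, v), val in self.passages.items():
            key = (u, v) if u <= v else (v, u)
            out[key] = out.get(key, 0.0) + val
        return out


def bounded_expected_passages(spec: AbsorbingChainSpec) -> EdgeRelevanceTable:
    """Expected edge passages / node visits within ``l_max`` steps (exact DP)."""
    T = spec.T
    n = T.n
    absorbing_idx = np.array(sorted(T.index[a] for a in spec.absorbing))
    transient_mask = np.ones(n, dtype=bool)
    transient_mask[absorbing_idx] = False

    alpha = np.zeros(n)
    alpha[T.index[spec.start]] = 1.0
    visits = np.zeros(n)
    M = T.matrix.T.tocsr()  # column-stochastic: M @ alpha propagates one step
    for _ in range(spec.l_max):
        visits += alpha
        alpha = M @ alpha
        alpha[~transient_mask] = 0.0  # mass reaching an absorbing seed stops
        if alpha.sum() < 1e-15:
            break

    passages: dict[tuple[str, str], float] = {}
    mat = T.matrix
    for i in np.flatnonzero(visits > 0):
        row = mat.getrow(i)
        for j, tij in zip(row.indices, row.data):
            if i == j:
                continue
            passages[(T.nodes[i], T.nodes[j])] = visits[i] * tij
    visit_map = {T.nodes[i]: float(visits[i]) for i in np.flatnonzero(visits > 0)}
    return EdgeRelevanceTable(T.nodes, passages, visit_map)


def aggregate_relevance(
    net: nx.Graph, seeds, T: TransitionMatrix, l_max: int = DEFAULT_L_MAX
) -> EdgeRelevanceTable:
    """Average the per-start passage tables over every mapped seed as start."""
    mapped = sorted(set(seeds) & set(T.index))
    if len(mapped) < 2:
        raise ValueError(f"need >= 2 mapped seeds for lateral walks, got {len(mapped)}")
    total_pass: dict[tuple[str, str], float] = {}
    total_vis: dict[str, float] = {}
    for start in mapped:
        spec = AbsorbingChainSpec(T, start, frozenset(s for s in mapped if s != start), l_max)
        table = bounded_expected_passages(spec)
        for e, v in table.passages.items():
            total_pass[e] = total_pass.get(e, 0.0) + v
        for node, v in table.visits.items():
            total_vis[node] = total_vis.get(node, 0.0) + v
    m = float(len(mapped))
    return EdgeRelevanceTable(
        T.nodes,
        {e: v / m for e, v in total_pass.items()},
        {k: v / m for k, v in total_vis.items()},
    )


def _count_connected_seed_pairs(sub: nx.Graph, seeds: list[str]) -> int:
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(nx.connected_components(sub)):
        for node in comp:
            comp_of[node] = ci
    return sum(
        1
        for a, b in combinations(seeds, 2)
        if a in comp_of and b in comp_of and comp_of[a] == comp_of[b]
    )


def extract_subnetwork(
    net: nx.Graph,
    relevance: EdgeRelevanceTable,
    seeds,
    objective: Callable[[nx.Graph, list[str]], float] | None = None,
) -> nx.Graph:
    """Extract the relevant subnetwork by automatic relevance thresholding.

    The objective scored at each candidate threshold defaults to the number of
    seed pairs connected in the retained graph; a custom
    ``objective(subgraph, seeds) -> score`` may be supplied.  Scanning runs
    from the largest distinct relevance downward and keeps the first (largest)
    threshold achieving the maximal score, i.e. ties break toward fewer edges.
    """
    mapped = sorted(set(seeds) & set(net.nodes))
    rel = {
        e: v
        for e, v in relevance.undirected().items()
        if net.has_edge(*e)
    }
    score_fn = objective or _count_connected_seed_pairs

    thresholds = sorted({v for v in rel.values() if v > 0}, reverse=True)
    best_theta = None
    best_score = -np.inf
    for theta in thresholds:
        sub = nx.Graph()
        sub.add_nodes_from(mapped)
        sub.add_edges_from(e for e, v in rel.items() if v >= theta)
        score = score_fn(sub, mapped)
        if score > best_score:  # strict: first (largest) theta wins ties
            best_score = score
            best_theta = theta

    result = nx.Graph()
    result.add_nodes_from(mapped)
    if best_theta is not None:
        result.add_edges_from(e for e, v in rel.items() if v >= best_theta)

    # restrict to components containing at least one seed
    keep: set[str] = set()
    seed_set = set(mapped)
    for comp in nx.connected_components(result):
        if comp & seed_set:
            keep |= comp
    result = result.subgraph(keep).copy()
    if _count_connected_seed_pairs(result, mapped) == 0 and len(mapped) > 1:
        logger.warning("extract_subnetwork: no seed pair is connected at the chosen threshold")
    return result
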