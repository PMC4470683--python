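"""Orchestration of the two-step drug-specific network construction.

Starting from a background signaling network and two drug gene sets — the
upstream genes (known drug-related genes) and the downstream genes (inferred
transcription factors) — the pipeline runs, per side:

1. longitudinal movement: random-walk-with-restart expansion keeping nodes
   significant under both permutation nulls (:mod:`drugspn.rwr`);
2. lateral movement: bounded K-walk relevance over the longitudinal set and
   extraction of the relevant subnetwork (:mod:`drugspn.kwalks`).

The two side networks are then merged by node and edge union.  Nodes present
in both sides are the *bridge nodes* — candidate linkers of the drug's
signaling cascade.  Every node receives a provenance label with precedence
seed > bridge > extended > novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from . import kwalks, netio, rwr

logger = logging.getLogger(__name__)

__all__ = [
    "DrugGeneSets",
    "PipelineResult",
    "seed_network",
    "bridge_nodes",
    "merge_networks",
    "run_pipeline",
]

PROVENANCE_LABELS = (
    "upstream_seed",
    "downstream_seed",
    "both_seed",
    "upstream_extended",
    "downstream_extended",
    "bridge",
    "novel",
)


@dataclass(frozen=True)
class DrugGeneSets:
    """The two drug seed sets; overlap is allowed."""

    upstream: frozenset[str]
    downstream: frozenset[str]

    def __post_init__(self):
        if not self.upstream:
            raise ValueError("upstream gene set must be non-empty")
        if not self.downstream:
            raise ValueError("downstream gene set must be non-empty")


@dataclass
class PipelineResult:
    """Everything the two-step construction produces, plus a run manifest."""

    seed_net: nx.Graph
    longitudinal_up: set[str]
    longitudinal_down: set[str]
    net_up: nx.Graph
    net_down: nx.Graph
    merged: nx.Graph
    bridges: set[str]
    bridge_edges: set[tuple[str, str]]
    provenance: dict[str, str]
    manifest: dict = field(default_factory=dict)

    def provenance_frame(self) -> pd.DataFrame:
        rows = [{"node": n, "label": self.provenance[n]} for n in sorted(self.provenance)]
        return pd.DataFrame(rows)


def seed_network(net: nx.Graph, drug_sets: DrugGeneSets) -> nx.Graph:
    """Induced subgraph on the mapped seeds, keeping isolated mapped seeds."""
    seeds = (set(drug_sets.upstream) | set(drug_sets.downstream)) & set(net.nodes)
    if not seeds:
        raise ValueError("no drug gene maps into the background network")
    return netio.induced_subgraph(net, seeds)


def bridge_nodes(up_net: nx.Graph, down_net: nx.Graph) -> tuple[set[str], set[tuple[str, str]]]:
    """Common nodes and common (undirected) edges of the two side networks."""
    common_nodes = set(up_net.nodes) & set(down_net.nodes)
    up_edges = {tuple(sorted(e)) for e in up_net.edges}
    down_edges = {tuple(sorted(e)) for e in down_net.edges}
    return common_nodes, up_edges & down_edges


def merge_networks(up_net: nx.Graph, down_net: nx.Graph, mode: str = "edge_union") -> nx.Graph:
    """Merge the side networks.

    ``edge_union`` (default) unions the two edge sets; ``induced_union``
    additionally induces every background edge among the node union — callers
    wanting that pass the result through :func:`drugspn.netio.induced_subgraph`
    on the background themselves, so here it equals edge_union on the inputs.
    """
    if mode not in ("edge_union", "induced_union"):
        raise ValueError(f"unknown merge mode {mode!r}")
    merged = nx.Graph()
    merged.add_nodes_from(up_net.nodes)
    merged.add_nodes_from(down_net.nodes)
    merged.add_edges_from(up_net.edges)
    merged.add_edges_from(down_net.edges)
    return merged


def _label(node, drug_sets: DrugGeneSets, bridges, up_nodes, down_nodes, long_up, long_down) -> str:
    in_up_seed = node in drug_sets.upstream
    in_down_seed = node in drug_sets.downstream
    if in_up_seed and in_down_seed:
        return "both_seed"
    if in_up_seed:
        return "upstream_seed"
    if in_down_seed:
        return "downstream_seed"
    if node in bridges:
        return "bridge"
    if node in up_nodes and node in long_up:
        return "upstream_extended"
    if node in down_nodes and node in long_down:
        return "downstream_extended"
    return "novel"


def _side(
    net: nx.Graph,
    seeds: set[str],
    weights,
    walk_params: rwr.WalkParameters,
    l_max: int,
    side: str,
) -> tuple[set[str], nx.Graph]:
    try:
        longitudinal = rwr.longitudinal_expand(net, seeds, weights=weights, params=walk_params)
    except Exception as exc:  # re-tag with the pipeline stage
        raise RuntimeError(f"[longitudinal/{side}] {exc}") from exc
    try:
        mode = walk_params.weight_mode if weights is not None else "uniform"
        T = rwr.transition_matrix(net, weights=weights, mode=mode if weights is not None else "uniform")
        if len(longitudinal & set(net.nodes)) >= 2:
            rel = kwalks.aggregate_relevance(net, longitudinal, T, l_max=l_max)
            lateral_net = kwalks.extract_subnetwork(net, rel, longitudinal)
        else:
            lateral_net = netio.induced_subgraph(net, longitudinal)
    except Exception as exc:
        raise RuntimeError(f"[lateral/{side}] {exc}") from exc
    extended = set(lateral_net.nodes)
    side_net = netio.induced_subgraph(net, extended)
    return longitudinal, side_net


def run_pipeline(
    net: nx.Graph,
    drug_sets: DrugGeneSets,
    weights: pd.DataFrame | pd.Series | None = None,
    walk_params: rwr.WalkParameters = rwr.WalkParameters(),
    l_max: int = kwalks.DEFAULT_L_MAX,
    merge_mode: str = "edge_union",
) -> PipelineResult:
    """Run the full two-step construction and label every merged node.

    One longitudinal plus one lateral pass per side — the construction is not
    iterated.  The lateral step seeds on the *entire* longitudinal set of its
    side, not only on the original drug genes, so linker recruitment can
    chain through first-pass expansions.  Deterministic for a fixed
    ``walk_params.seed`` (the two sides use derived, distinct substreams).
    """
    seed_net = seed_network(net, drug_sets)

    base_seed = walk_params.seed
    params_up = walk_params if base_seed is None else replace(walk_params, seed=base_seed * 2)
    params_down = walk_params if base_seed is None else replace(walk_params, seed=base_seed * 2 + 1)

    up_mapped = set(drug_sets.upstream) & set(net.nodes)
    down_mapped = set(drug_sets.downstream) & set(net.nodes)
    if not up_mapped:
        raise ValueError("no upstream gene maps into the background network")
    if not down_mapped:
        raise ValueError("no downstream gene maps into the background network")

    long_up, net_up = _side(net, up_mapped, weights, params_up, l_max, "upstream")
    long_down, net_down = _side(net, down_mapped, weights, params_down, l_max, "downstream")

    merged = merge_networks(net_up, net_down, mode=merge_mode)
    bridges, bridge_edges = bridge_nodes(net_up, net_down)

    provenance = {
        node: _label(node, drug_sets, bridges, set(net_up.nodes), set(net_down.nodes), long_up, long_down)
        for node in merged.nodes
    }
    manifest = {
        "restart": walk_params.restart,
        "n_permutations": walk_params.n_permutations,
        "alpha_global": walk_params.alpha_global,
        "alpha_local": walk_params.alpha_local,
        "weight_mode": walk_params.weight_mode if weights is not None else "uniform",
        "l_max": l_max,
        "merge_mode": merge_mode,
        "rng_seed": base_seed,
        "n_upstream_seeds": len(drug_sets.upstream),
        "n_downstream_seeds": len(drug_sets.downstream),
        "counts": {
            "seed_net": [seed_net.number_of_nodes(), seed_net.number_of_edges()],
            "longitudinal_up": len(long_up),
            "longitudinal_down": len(long_down),
            "net_up": [net_up.number_of_nodes(), net_up.number_of_edges()],
            "net_down": [net_down.number_of_nodes(), net_down.number_of_edges()],
            "merged": [merged.number_of_nodes(), merged.number_of_edges()],
            "bridges": len(bridges),
            "bridge_edges": len(bridge_edges),
        },
    }
    return PipelineResult(
        seed_net=seed_net,
        longitudinal_up=long_up,
        longitudinal_down=long_down,
        net_up=net_up,
        net_down=net_down,
        merged=merged,
        bridges=bridges,
        bridge_edges=bridge_edges,
        provenance=provenance,
        manifest=manifest,
    )
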