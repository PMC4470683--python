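"""Longitudinal movement: random walk with restart and empirical significance.

The walk iterates ``p <- (1 - r) * W p + r * p0`` with restart probability
``r`` (default 0.5) and ``p0`` uniform over the mapped seed genes; ``W`` is
the column-stochastic transpose of the row-stochastic transition matrix.  In
``node_weighted`` mode the probability of stepping from i to a neighbor j is
proportional to j's functional-similarity weight, biasing propagation toward
genes functionally close to the drug's upstream set; ``uniform`` mode is the
plain degree-normalized walk.

Significance of a node's stationary score is assessed against two empirical
nulls, both with the add-one correction so p stays in (0, 1]:

* global — permuted seed sets drawn uniformly from all network nodes;
* local — permuted seed sets drawn degree-matched (each real seed replaced by
  a random node from its degree bin), discounting pure degree artifacts.

A node is recruited into the expanded ("longitudinal") set when both p-values
fall below the threshold (default 0.05 each); mapped seeds are always kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "WalkParameters",
    "TransitionMatrix",
    "transition_matrix",
    "rwr_scores",
    "walk_significance",
    "longitudinal_expand",
]


@dataclass(frozen=True)
class WalkParameters:
    """Tunables of the restart walk and its permutation nulls."""

    restart: float = 0.5
    tol: float = 1e-10  # L1 convergence tolerance
    max_iter: int = 1000
    weight_mode: str = "uniform"  # or "node_weighted"
    n_permutations: int = 1000
    n_degree_bins: int = 10
    alpha_global: float = 0.05
    alpha_local: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.restart <= 1.0):
            raise ValueError(f"restart probability must be in (0, 1], got {self.restart}")
        if self.weight_mode not in ("uniform", "node_weighted"):
            raise ValueError(f"unknown weight mode {self.weight_mode!r}")


@dataclass
class TransitionMatrix:
    """Row-stochastic transition structure over an ordered node list."""

    nodes: list[str]
    matrix: sp.csr_matrix  # matrix[i, j] = P(i -> j)
    index: dict[str, int] = field(init=False)
    degrees: np.ndarray = field(init=False)

    def __post_init__(self):
        self.index = {n: i for i, n in enumerate(self.nodes)}
        adj = self.matrix != 0
        self.degrees = np.asarray(adj.sum(axis=1)).ravel()
        # self-absorbing isolated rows have degree 0 for binning purposes
        diag = self.matrix.diagonal()
        self.degrees[diag == 1.0] = 0

    @property
    def n(self) -> int:
        return len(self.nodes)


def transition_matrix(
    net: nx.Graph,
    weights: pd.Series | pd.DataFrame | None = None,
    mode: str = "uniform",
) -> TransitionMatrix:
    """Build the row-stochastic walk matrix for *net*.

    In ``node_weighted`` mode the step probability i -> j is proportional to
    the target node's weight among i's neighbors; rows whose neighbor weights
    sum to zero fall back to uniform (logged).  Isolated nodes self-absorb.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot build a transition matrix for an empty network")
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    w = np.ones(n)
    if mode == "node_weighted":
        if weights is None:
            raise ValueError("node_weighted mode requires a weight table")
        if isinstance(weights, pd.DataFrame):
            weights = weights["weight"]
        w = np.array([float(weights.get(node, np.nan)) for node in nodes])
        bad = ~np.isfinite(w) | (w < 0)
        if bad.any():
            pos = w[~bad & (w > 0)]
            fill = float(pos.min()) if len(pos) else 1.0
            logger.info("transition_matrix: %d node weight(s) missing, filled with %g", bad.sum(), fill)
            w[bad] = fill
    elif mode != "uniform":
        raise ValueError(f"unknown weight mode {mode!r}")

    rows, cols, vals = [], [], []
    n_fallback = 0
    for node in nodes:
        i = idx[node]
        nbrs = [idx[v] for v in net.neighbors(node)]
        if not nbrs:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            continue
        nw = w[nbrs]
        total = nw.sum()
        if total <= 0:
            n_fallback += 1
            nw = np.ones(len(nbrs))
            total = float(len(nbrs))
        for j, wj in zip(nbrs, nw):
            rows.append(i)
            cols.append(j)
            vals.append(wj / total)
    if n_fallback:
        logger.warning("transition_matrix: %d row(s) fell back to uniform (zero neighbor weights)", n_fallback)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(nodes, mat)


def _restart_vector(T: TransitionMatrix, seeds) -> tuple[np.ndarray, list[str]]:
    mapped = sorted(set(seeds) & set(T.index))
    if not mapped:
        raise ValueError(f"no seed maps into the network; unmapped: {sorted(set(seeds))}")
    p0 = np.zeros(T.n)
    p0[[T.index[s] for s in mapped]] = 1.0 / len(mapped)
    return p0, mapped


def _iterate(W: sp.csr_matrix, P0: np.ndarray, r: float, tol: float, max_iter: int) -> np.ndarray:
    """Power iteration of the restart walk; accepts a matrix of start vectors."""
    P = P0.copy()
    for _ in range(max_iter):
        P_next = (1.0 - r) * (W @ P) + r * P0
        delta = np.abs(P_next - P).sum(axis=0).max()
        P = P_next
        if delta < tol:
            break
    return P


def rwr_scores(
    T: TransitionMatrix, seeds, params: WalkParameters = WalkParameters()
) -> pd.DataFrame:
    """Stationary restart-walk scores for one seed set.

    Returns a DataFrame indexed by node with columns ``score`` and ``is_seed``;
    scores sum to 1.
    """
    p0, mapped = _restart_vector(T, seeds)
    W = T.matrix.T.tocsr()
    p = _iterate(W, p0[:, None], params.restart, params.tol, params.max_iter)[:, 0]
    return pd.DataFrame(
        {"score": p, "is_seed": [n in set(mapped) for n in T.nodes]}, index=pd.Index(T.nodes, name="node")
    )


def _degree_bins(degrees: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign nodes to degree bins of near-equal occupancy (rank-based)."""
    order = np.argsort(degrees, kind="stable")
    bins = np.empty(len(degrees), dtype=int)
    # equal-frequency binning, but nodes with identical degree share a bin
    raw = (np.arange(len(degrees)) * n_bins) // max(len(degrees), 1)
    bins[order] = raw
    # merge ties: same degree -> bin of first occurrence
    deg_to_bin: dict[int, int] = {}
    for i in order:
        d = int(degrees[i])
        if d not in deg_to_bin:
            deg_to_bin[d] = bins[i]
        bins[i] = deg_to_bin[d]
    return bins


def _null_seed_matrix(
    T: TransitionMatrix,
    mapped: list[str],
    n_perm: int,
    rng: np.random.Generator,
    degree_matched: bool,
    n_bins: int,
) -> np.ndarray:
    """Matrix of restart vectors (n_nodes x n_perm) for permuted seed sets."""
    n = T.n
    k = len(mapped)
    P0 = np.zeros((n, n_perm))
    if not degree_matched:
        for c in range(n_perm):
            pick = rng.choice(n, size=k, replace=False)
            P0[pick, c] = 1.0 / k
        return P0
    bins = _degree_bins(T.degrees, n_bins)
    members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }
    seed_idx = [T.index[s] for s in mapped]
    lone = [s for s, i in zip(mapped, seed_idx) if len(members[bins[i]]) == 1]
    if lone:
        logger.info(
            "walk_significance: %d seed(s) alone in their degree bin map to themselves "
            "in local permutations: %s", len(lone), ", ".join(lone[:5]),
        )
    for c in range(n_perm):
        chosen: set[int] = set()
        for i in seed_idx:
            pool = members[bins[i]]
            pick = int(pool[rng.integers(len(pool))])
            # avoid collapsing two seeds onto one node where the bin allows
            tries = 0
            while pick in chosen and tries < 10 * len(pool):
                pick = int(pool[rng.integers(len(pool))])
                tries += 1
            chosen.add(pick)
        idx = np.fromiter(chosen, dtype=int)
        P0[idx, c] = 1.0 / len(idx)
    return P0


def walk_significance(
    T: TransitionMatrix, seeds, params: WalkParameters = WalkParameters()
) -> pd.DataFrame:
    """Restart-walk scores with empirical global and local p-values.

    ``p = (1 + #{null score >= observed}) / (n_permutations + 1)`` per node,
    with the global null drawing seed sets uniformly and the local null
    drawing them degree-matched.  Bitwise reproducible for a fixed
    ``params.seed``.
    """
    if params.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1 for significance estimates")
    rng = np.random.default_rng(params.seed)
    p0, mapped = _restart_vector(T, seeds)
    W = T.matrix.T.tocsr()
    obs = _iterate(W, p0[:, None], params.restart, params.tol, params.max_iter)[:, 0]

    out = pd.DataFrame(
        {"score": obs, "is_seed": [n in set(mapped) for n in T.nodes]},
        index=pd.Index(T.nodes, name="node"),
    )
    for label, degree_matched in (("global_p", False), ("local_p", True)):
        P0 = _null_seed_matrix(T, mapped, params.n_permutations, rng, degree_matched, params.n_degree_bins)
        null = _iterate(W, P0, params.restart, params.tol, params.max_iter)
        exceed = (null >= obs[:, None]).sum(axis=1)
        out[label] = (1.0 + exceed) / (params.n_permutations + 1.0)
    return out


def longitudinal_expand(
    net: nx.Graph,
    seeds,
    weights: pd.DataFrame | pd.Series | None = None,
    params: WalkParameters = WalkParameters(),
) -> set[str]:
    """Expand a seed set along the network by significant propagation.

    Returns the mapped seeds plus every node significant under both the
    global and the local permutation null.
    """
    mode = params.weight_mode
    if weights is not None and mode == "uniform":
        mode = "node_weighted"
        params = replace(params, weight_mode=mode)
    T = transition_matrix(net, weights=weights, mode=mode)
    table = walk_significance(T, seeds, params)
    mapped = set(table.index[table["is_seed"]])
    sig = set(
        table.index[
            (table["global_p"] < params.alpha_global) & (table["local_p"] < params.alpha_local)
        ]
    )
    return sig | mapped
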