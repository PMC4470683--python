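"""Independent reference implementations used to cross-check the package.

Each oracle derives its answer by a different route than the code under test:
direct linear algebra for the restart walk, vectorized walk simulation for
bounded passage counts, exhaustive clique enumeration with union-find for
clique percolation, and exact rational draw enumeration for the
hypergeometric tail.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def linear_solve_scores(T, seeds, r):
    """Restart-walk stationary scores by direct matrix inversion."""
    n = T.n
    p0 = np.zeros(n)
    mapped = [T.index[s] for s in seeds if s in T.index]
    p0[mapped] = 1.0 / len(mapped)
    W = T.matrix.T.toarray()
    return np.linalg.solve(np.eye(n) - (1 - r) * W, r * p0)


def monte_carlo_passages(T, start, absorbing, l_max, n_walks, seed):
    """Simulate absorbing walks; per directed edge return (mean, SE).

    Vectorized over walkers; per-walk passage counts give an honest standard
    error for each edge mean.
    """
    rng = np.random.default_rng(seed)
    n = T.n
    P = T.matrix.toarray()
    cum = np.cumsum(P, axis=1)
    absorbing_idx = np.zeros(n, dtype=bool)
    for a in absorbing:
        absorbing_idx[T.index[a]] = True

    pos = np.full(n_walks, T.index[start])
    alive = np.ones(n_walks, dtype=bool)
    counts = {}  # directed edge -> per-walk count array (uint8)
    for _ in range(l_max):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        cur = pos[idx]
        u = rng.random(idx.size)
        nxt = (cum[cur] < u[:, None]).sum(axis=1)
        for a, b in set(zip(cur.tolist(), nxt.tolist())):
            mask = (cur == a) & (nxt == b)
            key = (T.nodes[a], T.nodes[b])
            if key not in counts:
                counts[key] = np.zeros(n_walks, dtype=np.uint8)
            counts[key][idx[mask]] += 1
        pos[idx] = nxt
        alive[idx[absorbing_idx[nxt]]] = False

    out = {}
    for key, c in counts.items():
        mean = c.mean()
        se = c.std(ddof=1) / np.sqrt(n_walks)
        out[key] = (float(mean), float(se))
    return out


def brute_force_cpm(g, k=3):
    """Clique percolation by enumerating every k-clique + union-find."""
    nodes = sorted(g.nodes)
    cliques = [
        frozenset(c)
        for c in combinations(nodes, k)
        if all(g.has_edge(u, v) for u, v in combinations(c, 2))
    ]
    parent = {c: c for c in cliques}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in combinations(cliques, 2):
        if len(a & b) >= k - 1:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups = {}
    for c in cliques:
        groups.setdefault(find(c), set()).update(c)
    return sorted(groups.values(), key=lambda s: (-len(s), tuple(sorted(s))))


def enumeration_tail_table(N, K, n):
    """Exact P(X >= k) for every k, by enumerating all C(N, n) draws."""
    total = 0
    max_k = min(K, n)
    overlap_counts = [0] * (max_k + 1)
    for draw in combinations(range(N), n):
        total += 1
        overlap_counts[sum(1 for i in draw if i < K)] += 1
    tails = []
    running = 0
    for k in range(max_k, -1, -1):
        running += overlap_counts[k]
        tails.append(Fraction(running, total))
    tails.reverse()
    return tails  # tails[k] = P(X >= k)
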