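"""Functional-similarity node weights from an ontology DAG.

Each node of the background network is weighted by its Gene Ontology-style
functional similarity to the drug's upstream gene set.  Per annotation domain
k (MF, BP, CC) a node i receives

    Score_i(k) = (1/n) * sum_j sim(i, j)

over the n upstream genes j with a computable similarity, and the final weight
is the mean over the N domains that produced a score:

    S_hat(i) = (1/N) * sum_k Score_i(k)

Term-level similarity is the Wang graph-based measure: each term's semantic
value is the sum of contributions of its ancestors, discounted multiplicatively
along parent edges (default factors 0.8 for ``is_a``, 0.6 for ``part_of``),
and two terms are compared through their shared ancestors.  Gene-level
similarity aggregates the pairwise term matrix by best-match average.  The
measure is pluggable: any ``(terms_a, terms_b, dag) -> float | nan`` callable
can replace the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAINS",
    "OntologyDAG",
    "load_ontology",
    "load_annotations",
    "term_semantic_values",
    "term_similarity",
    "best_match_average",
    "gene_similarity",
    "node_weights",
    "fill_missing_weights",
]

DOMAINS = ("MF", "BP", "CC")
RELATIONS = ("is_a", "part_of")

DEFAULT_W_IS_A = 0.8
DEFAULT_W_PART_OF = 0.6


@dataclass
class OntologyDAG:
    """Parent links and domain labels for an ontology term set.

    ``parents`` maps a term to ``{(parent_term, relation), ...}``; roots have
    an empty set.  Every term carries one domain label.  The graph must be
    acyclic (checked on construction).
    """

    parents: dict[str, set[tuple[str, str]]]
    domain: dict[str, str]
    _sv_cache: dict[tuple[str, float, float], dict[str, float]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self):
        for term, links in self.parents.items():
            for parent, rel in links:
                if rel not in RELATIONS:
                    raise ValueError(f"term {term}: unknown relation {rel!r}")
                if parent not in self.parents:
                    raise ValueError(f"term {term}: parent {parent} not in DAG")
                if self.domain.get(parent) != self.domain.get(term):
                    raise ValueError(f"edge {term}->{parent} crosses domains")
        missing = set(self.parents) - set(self.domain)
        if missing:
            raise ValueError(f"terms without a domain label: {sorted(missing)[:5]}")
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t, stack):
            state[t] = 0
            for p, _ in self.parents[t]:
                if state.get(p) == 0:
                    raise ValueError(f"ontology cycle through {p}")
                if p not in state:
                    visit(p, stack)
            state[t] = 1

        for t in self.parents:
            if t not in state:
                visit(t, [])

    @property
    def terms(self) -> set[str]:
        return set(self.parents)


def load_ontology(path) -> OntologyDAG:
    """Read an OBO-subset TSV: ``term<TAB>parent<TAB>relation<TAB>domain``.

    Roots use an empty/``-`` parent field.  Comment lines start with ``#``.
    """
    parents: dict[str, set[tuple[str, str]]] = {}
    domain: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            term, parent, rel, dom = (f.strip() for f in fields)
            if dom not in DOMAINS:
                raise ValueError(f"{path}:{lineno}: unknown domain {dom!r}")
            parents.setdefault(term, set())
            domain.setdefault(term, dom)
            if parent and parent != "-":
                parents.setdefault(parent, set())
                domain.setdefault(parent, dom)
                parents[term].add((parent, rel))
    return OntologyDAG(parents, domain)


def load_annotations(path) -> dict[str, set[str]]:
    """Read a GAF-like TSV (``gene<TAB>term``) into gene -> term set."""
    annot: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            annot.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return annot


def term_semantic_values(
    dag: OntologyDAG,
    term: str,
    w_is_a: float = DEFAULT_W_IS_A,
    w_part_of: float = DEFAULT_W_PART_OF,
) -> dict[str, float]:
    """Wang S-values of *term* and all its ancestors.

    S(term) = 1; walking upward, each ancestor a gets
    S(a) = max over child edges (a <- c) on ancestor paths of w_edge * S(c).
    """
    key = (term, w_is_a, w_part_of)
    cached = dag._sv_cache.get(key)
    if cached is not None:
        return cached
    if term not in dag.parents:
        raise KeyError(f"term {term!r} not in ontology")
    w = {"is_a": w_is_a, "part_of": w_part_of}
    sval = {term: 1.0}
    # process terms in order of decreasing S so maxima settle without iteration
    frontier = [term]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for parent, rel in dag.parents[t]:
                cand = w[rel] * sval[t]
                if cand > sval.get(parent, 0.0):
                    sval[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    dag._sv_cache[key] = sval
    return sval


def term_similarity(
    dag: OntologyDAG,
    t1: str,
    t2: str,
    w_is_a: float = DEFAULT_W_IS_A,
    w_part_of: float = DEFAULT_W_PART_OF,
) -> float:
    """Wang similarity of two terms in the same domain, in [0, 1]."""
    if dag.domain[t1] != dag.domain[t2]:
        raise ValueError(
            f"terms from different domains: {t1} ({dag.domain[t1]}) vs {t2} ({dag.domain[t2]})"
        )
    if t1 == t2:
        return 1.0
    sa = term_semantic_values(dag, t1, w_is_a, w_part_of)
    sb = term_semantic_values(dag, t2, w_is_a, w_part_of)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


def best_match_average(sim: list[list[float]]) -> float:
    """Aggregate a pairwise similarity matrix by best-match average.

    ``(sum of row maxima + sum of column maxima) / (rows + columns)``.
    """
    n_rows = len(sim)
    n_cols = len(sim[0])
    best_rows = sum(max(row) for row in sim)
    best_cols = sum(max(sim[i][j] for i in range(n_rows)) for j in range(n_cols))
    return (best_rows + best_cols) / (n_rows + n_cols)


def gene_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    dag: OntologyDAG,
    w_is_a: float = DEFAULT_W_IS_A,
    w_part_of: float = DEFAULT_W_PART_OF,
) -> float:
    """Best-match-average over the pairwise Wang term matrix.

    Returns ``nan`` (missing) when either term set is empty.
    """
    ta = sorted(set(terms_a))
    tb = sorted(set(terms_b))
    if not ta or not tb:
        return math.nan
    sim = [[term_similarity(dag, a, b, w_is_a, w_part_of) for b in tb] for a in ta]
    return best_match_average(sim)


def _domain_terms(terms: set[str], dag: OntologyDAG, dom: str) -> set[str]:
    return {t for t in terms if t in dag.domain and dag.domain[t] == dom}


def node_weights(
    nodes: Iterable[str],
    upstream: Iterable[str],
    annot: Mapping[str, set[str]],
    dag: OntologyDAG,
    similarity: Callable[..., float] | None = None,
    w_is_a: float = DEFAULT_W_IS_A,
    w_part_of: float = DEFAULT_W_PART_OF,
) -> pd.DataFrame:
    """Per-node functional-similarity weights to the upstream gene set.

    Returns a DataFrame indexed by node with columns ``score_MF``, ``score_BP``,
    ``score_CC``, ``n_domains`` and ``weight`` (the cross-domain mean S-hat);
    domain scores and the weight are NaN where no similarity is computable.
    An upstream gene that is also a scored node contributes its
    self-similarity of 1.0 to its own mean.
    """
    upstream = sorted(set(upstream))
    if not upstream:
        raise ValueError("upstream gene set must be non-empty")
    sim = similarity or gene_similarity

    # cache upstream term sets per domain once
    up_terms = {
        dom: {j: _domain_terms(annot.get(j, set()), dag, dom) for j in upstream}
        for dom in DOMAINS
    }
    rows = []
    for node in sorted(set(nodes)):
        scores: dict[str, float] = {}
        for dom in DOMAINS:
            node_terms = _domain_terms(annot.get(node, set()), dag, dom)
            vals = []
            for j in upstream:
                s = sim(node_terms, up_terms[dom][j], dag, w_is_a, w_part_of)
                if not math.isnan(s):
                    vals.append(s)
            scores[dom] = sum(vals) / len(vals) if vals else math.nan
        have = [scores[d] for d in DOMAINS if not math.isnan(scores[d])]
        weight = sum(have) / len(have) if have else math.nan
        rows.append(
            {
                "node": node,
                "score_MF": scores["MF"],
                "score_BP": scores["BP"],
                "score_CC": scores["CC"],
                "n_domains": len(have),
                "weight": weight,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def fill_missing_weights(weights: pd.DataFrame) -> pd.Series:
    """Weight vector with missing entries set to the minimum positive weight.

    Keeps every node reachable when weights bias walk transitions; the number
    of substitutions is logged.  All-missing tables fall back to uniform 1.0.
    """
    w = weights["weight"].copy()
    missing = w.isna() | (w <= 0)
    positive = w[~missing]
    fill = float(positive.min()) if len(positive) else 1.0
    n = int(missing.sum())
    if n:
        logger.info("fill_missing_weights: substituted %d missing weight(s) with %g", n, fill)
    w[missing] = fill
    return w
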