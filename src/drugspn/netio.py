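"""Network and gene-set input/output.

Readers for the plain-text formats the pipeline consumes — SIF and 2/3-column
TSV edge lists, GMT gene sets, one-symbol-per-line gene lists — plus the graph
primitives (assembly, induced subgraphs, components) shared by every other
module.

The background signaling network and every derived subnetwork are simple
undirected :class:`networkx.Graph` objects over gene-symbol node labels.
Directionality present in source databases is deliberately discarded: all
downstream analyses (degree, hubs, clique percolation, undirected walks) are
orientation-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "ParseError",
    "load_interactions",
    "load_gene_list",
    "load_gene_sets",
    "write_gene_sets",
    "write_edge_list",
    "assemble_network",
    "induced_subgraph",
    "connected_components",
]


class ParseError(ValueError):
    """Raised for a malformed input line; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class InteractionRecord:
    """One pairwise interaction as read from file, order-preserving.

    ``same_complex`` marks pairs that co-occur only inside a protein complex;
    such pairs carry no signal-flow information and can be excluded at
    assembly time.
    """

    source: str
    target: str
    origin: str = ""
    same_complex: bool = False

    def __post_init__(self):
        if not self.source or not self.target:
            raise ValueError("interaction endpoints must be non-empty symbols")


_DIALECTS = ("sif", "tsv2", "tsv3")


def _iter_content_lines(path):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_interactions(path, dialect: str = "tsv2") -> list[InteractionRecord]:
    """Read interaction records from *path*.

    Dialects:

    ``sif``
        ``source<ws>relation<ws>target [target ...]`` — one record per
        (source, target) pair; the relation is kept as ``origin``.
    ``tsv2``
        ``source<TAB>target``.
    ``tsv3``
        ``source<TAB>target<TAB>same_complex`` with the flag as ``0``/``1``.

    Lines starting with ``#`` and blank lines are skipped.  An empty file
    yields an empty list.  Malformed lines raise :class:`ParseError` naming
    the line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    records: list[InteractionRecord] = []
    for lineno, line in _iter_content_lines(path):
        if dialect == "sif":
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(path, lineno, f"SIF line needs >=3 fields, got {len(fields)}")
            src, rel = fields[0], fields[1]
            for tgt in fields[2:]:
                records.append(InteractionRecord(src, tgt, origin=rel))
        else:
            fields = line.split("\t")
            want = 2 if dialect == "tsv2" else 3
            if len(fields) != want:
                raise ParseError(path, lineno, f"expected {want} columns, got {len(fields)}")
            same_complex = False
            if dialect == "tsv3":
                flag = fields[2].strip()
                if flag not in ("0", "1"):
                    raise ParseError(path, lineno, f"same_complex flag must be 0/1, got {flag!r}")
                same_complex = flag == "1"
            records.append(
                InteractionRecord(fields[0].strip(), fields[1].strip(), same_complex=same_complex)
            )
    return records


def load_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list (``#`` comments allowed).

    Order is preserved; duplicates are dropped keeping first occurrence.
    """
    seen = {}
    for _, line in _iter_content_lines(path):
        sym = line.strip()
        if sym and sym not in seen:
            seen[sym] = None
    return list(seen)


def load_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Empty sets are rejected; duplicate set names raise :class:`ParseError`.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in _iter_content_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "GMT line needs name, description and >=1 gene")
        name = fields[0].strip()
        if name in sets:
            raise ParseError(path, lineno, f"duplicate gene-set name {name!r}")
        genes = {g.strip() for g in fields[2:] if g.strip()}
        if not genes:
            raise ParseError(path, lineno, f"gene set {name!r} is empty")
        sets[name] = genes
    return sets


def write_gene_sets(sets: dict[str, Iterable[str]], path, description: str = "") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_edge_list(net: nx.Graph, path) -> None:
    """Write a 2-column TSV edge list, edges sorted for reproducibility."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def assemble_network(
    records: Sequence[InteractionRecord], exclude_same_complex: bool = True
) -> nx.Graph:
    """Merge interaction records into a simple undirected graph.

    Duplicate pairs collapse regardless of orientation, self-loops are dropped
    (count logged), and records flagged ``same_complex`` are excluded when
    *exclude_same_complex* is set — complex co-membership does not reveal the
    flow of signaling information.
    """
    net = nx.Graph()
    n_self = 0
    for rec in records:
        if exclude_same_complex and rec.same_complex:
            continue
        u = rec.source.strip()
        v = rec.target.strip()
        if u == v:
            n_self += 1
            continue
        net.add_edge(u, v)
    if n_self:
        logger.info("assemble_network: dropped %d self-loop record(s)", n_self)
    return net


def induced_subgraph(net: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Subgraph induced on ``keep ∩ net.nodes`` (a standalone copy)."""
    keep = set(keep) & set(net.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(keep)
    sub.add_edges_from((u, v) for u, v in net.edges(keep) if u in keep and v in keep)
    return sub


def connected_components(net: nx.Graph) -> list[set[str]]:
    """Components sorted by size descending, ties by smallest member."""
    comps = [set(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
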