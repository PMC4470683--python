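"""Enrichment and topology evaluation of a drug-specific network.

Covers gene-level GWAS association (minimum SNP p within the gene body plus a
flanking window, default 20 kb each side), exact upper-tail hypergeometric
enrichment against explicit backgrounds, Benjamini-Hochberg correction,
pathway-category abundance Z-scores, degree/hub statistics and 3-clique
percolation modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import k_clique_communities
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WINDOW",
    "EnrichmentResult",
    "load_snp_table",
    "load_gene_models",
    "gene_min_p",
    "related_genes",
    "hypergeom_test",
    "enrichment",
    "bh_adjust",
    "category_zscores",
    "degree_stats",
    "hub_nodes",
    "kclique_communities",
]

DEFAULT_WINDOW = 20_000  # bases up- and down-stream of the gene body
NOMINAL_P = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric enrichment with its full contingency counts."""

    N: int  # population size
    K: int  # population successes
    n: int  # sample size
    k: int  # sample successes
    p_value: float
    p_adjusted: float | None = None


def load_snp_table(path) -> pd.DataFrame:
    """Read a SNP association TSV: ``snp  chrom  pos  p`` (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["snp", "chrom", "pos", "p"])
    if df.iloc[0]["pos"] == "pos":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    try:
        df["pos"] = df["pos"].astype(int)
        df["p"] = df["p"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed SNP position or p-value column: {exc}") from exc
    return df


def load_gene_models(path) -> pd.DataFrame:
    """Read BED-like gene models: ``chrom  start  end  gene`` (0-based, half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "gene"])
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: {len(bad)} gene model(s) with start >= end")
    return df


def gene_min_p(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Minimum SNP p-value per gene within ``[start - window, end + window)``.

    The lower bound is closed, the upper open (matching 0-based half-open
    models).  Genes with no SNP in range get ``min_p = NaN`` and
    ``related = False``; otherwise ``related`` flags ``min_p < 0.05``.
    Invariant to SNP row order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    bad = snps[(snps["p"] <= 0) | (snps["p"] > 1)]
    if len(bad):
        raise ValueError(f"{len(bad)} SNP row(s) with p outside (0, 1]")
    out_rows = []
    by_chrom = {c: g.sort_values("pos") for c, g in snps.groupby("chrom")}
    for row in genes.itertuples(index=False):
        chrom_snps = by_chrom.get(row.chrom)
        min_p = np.nan
        if chrom_snps is not None:
            pos = chrom_snps["pos"].to_numpy()
            lo = np.searchsorted(pos, row.start - window, side="left")
            hi = np.searchsorted(pos, row.end + window, side="left")
            if hi > lo:
                min_p = float(chrom_snps["p"].to_numpy()[lo:hi].min())
        out_rows.append(
            {
                "gene": row.gene,
                "min_p": min_p,
                "related": bool(min_p < NOMINAL_P) if not np.isnan(min_p) else False,
            }
        )
    return pd.DataFrame(out_rows)


def related_genes(assoc: pd.DataFrame, threshold: float = NOMINAL_P) -> set[str]:
    """Genes whose minimum SNP p-value is below *threshold*."""
    keep = assoc["min_p"].notna() & (assoc["min_p"] < threshold)
    return set(assoc.loc[keep, "gene"])


def hypergeom_test(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Drawing *n* items from a population of *N* containing *K* successes;
    computed by summing the log-pmf, so it stays accurate far into the tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if k < 0 or k > min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # sum the pmf over the tail in log space; sf() alone underflows to 0
    # beyond ~1e-308 while the log-pmf stays finite
    ks = np.arange(k, min(K, n) + 1)
    logp = hypergeom.logpmf(ks, N, K, n)
    return float(np.exp(logsumexp(logp)))


def enrichment(
    sample: set[str], successes: set[str], population: set[str]
) -> EnrichmentResult:
    """Hypergeometric enrichment of *successes* in *sample* over *population*.

    Sample and success genes outside the population are excluded first; the
    background is an explicit argument so the same sample can be tested
    against the genome, the background network, or a genotyped-gene set.
    """
    pop = set(population)
    samp = set(sample) & pop
    succ = set(successes) & pop
    k = len(samp & succ)
    p = hypergeom_test(len(pop), len(succ), len(samp), k)
    return EnrichmentResult(len(pop), len(succ), len(samp), k, p)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def category_zscores(counts: Mapping[str, int], ddof: int = 0) -> pd.DataFrame:
    """Relative pathway abundance per category: Z = (x - u) / sigma.

    *u* and *sigma* are the mean and (population, ``ddof=0``) standard
    deviation of the per-category pathway counts at one annotation level.
    Categories with Z > 0 are flagged ``selected``.
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 categories for a Z-score")
    labels = sorted(counts)
    x = np.array([counts[c] for c in labels], dtype=float)
    sigma = float(x.std(ddof=ddof))
    if sigma == 0:
        raise ValueError("all categories have the same count; Z-scores undefined (sigma = 0)")
    u = float(x.mean())
    z = (x - u) / sigma
    return pd.DataFrame({"category": labels, "count": x.astype(int), "z": z, "selected": z > 0})


def degree_stats(net: nx.Graph) -> tuple[pd.Series, float, pd.Series]:
    """Per-node degrees, mean degree (= 2|E|/|V|) and a degree histogram."""
    if net.number_of_nodes() == 0:
        raise ValueError("degree statistics of an empty network are undefined")
    deg = pd.Series(dict(net.degree()), name="degree").sort_index()
    mean = 2.0 * net.number_of_edges() / net.number_of_nodes()
    hist = deg.value_counts().sort_index()
    hist.index.name = "degree"
    return deg, mean, hist


def hub_nodes(
    net: nx.Graph, cutoff: int | None = None, quantile: float | None = None
) -> set[str]:
    """Nodes with degree strictly greater than the cutoff.

    Either an explicit *cutoff* or a *quantile* strategy must be given; the
    quantile strategy sets the cutoff to the smallest degree whose empirical
    CDF reaches *quantile*.
    """
    if (cutoff is None) == (quantile is None):
        raise ValueError("give exactly one of cutoff= or quantile=")
    deg = dict(net.degree())
    if quantile is not None:
        if not (0 < quantile <= 1):
            raise ValueError("quantile must be in (0, 1]")
        values = np.sort(np.fromiter(deg.values(), dtype=int))
        cdf = np.arange(1, len(values) + 1) / len(values)
        cutoff = int(values[np.searchsorted(cdf, quantile, side="left")])
    return {node for node, d in deg.items() if d > cutoff}


def kclique_communities(net: nx.Graph, k: int = 3) -> list[set[str]]:
    """Overlapping modules by k-clique percolation (default k = 3).

    Communities are unions of maximal cliques of size >= k chained by
    (k-1)-node overlaps, so every module node sits in at least one k-vertex
    clique.  Deterministically ordered (size desc, then smallest member).
    """
    if k < 3:
        raise ValueError("clique percolation needs k >= 3")
    comms = [set(c) for c in k_clique_communities(net, k)]
    return sorted(comms, key=lambda c: (-len(c), tuple(sorted(c))))
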