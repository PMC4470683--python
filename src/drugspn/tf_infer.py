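"""Inference of drug downstream transcription factors.

Drug-induced expression enters as a ranked probe profile.  The top and bottom
``n_probes`` probes (default 100 each) are mapped to up- and down-regulated
gene sets, and each transcription factor's target set is tested for
over-representation in a regulated set with an upper-tail hypergeometric test
over the universe of all TF targets.  TFs with p below the nominal threshold
(default 0.05, uncorrected) are the drug's downstream genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "RankedExpressionProfile",
    "TFEnrichmentResult",
    "load_profile",
    "load_probe_map",
    "top_bottom_genes",
    "infer_tfs",
]


@dataclass
class RankedExpressionProfile:
    """Probes ordered by rank score (descending; ties broken by probe id)."""

    probes: list[str]
    scores: list[float]
    probe_to_gene: dict[str, str]

    def __post_init__(self):
        if len(self.probes) != len(self.scores):
            raise ValueError("probes and scores length mismatch")
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probe ids")
        order = sorted(range(len(self.probes)), key=lambda i: (-self.scores[i], self.probes[i]))
        self.probes = [self.probes[i] for i in order]
        self.scores = [self.scores[i] for i in order]

    def __len__(self):
        return len(self.probes)


@dataclass(frozen=True)
class TFEnrichmentResult:
    tf: str
    direction: str  # "up" | "down"
    k: int  # overlap
    K: int  # target-set size in universe
    n: int  # regulated-list size in universe
    N: int  # universe size
    p_value: float


def load_profile(path, probe_map: Mapping[str, str]) -> RankedExpressionProfile:
    """Read a ``probe<TAB>score`` TSV into a ranked profile."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "score"], comment="#")
    return RankedExpressionProfile(
        df["probe"].astype(str).tolist(),
        df["score"].astype(float).tolist(),
        dict(probe_map),
    )


def load_probe_map(path) -> dict[str, str]:
    """Read a ``probe<TAB>gene`` TSV mapping (first mapping wins)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], comment="#")
    out: dict[str, str] = {}
    for probe, gene in zip(df["probe"].astype(str), df["gene"].astype(str)):
        out.setdefault(probe, gene)
    return out


def top_bottom_genes(
    profile: RankedExpressionProfile, n_probes: int = 100
) -> tuple[set[str], set[str]]:
    """Map the top/bottom *n_probes* probes to up-/down-regulated gene sets.

    Probes without a gene mapping are dropped after selection, so a set may be
    smaller than *n_probes*.  A gene selected in both directions is removed
    from both (with a warning) — its direction is ambiguous.
    """
    if len(profile) < 2 * n_probes:
        raise ValueError(
            f"profile has {len(profile)} probes; need at least {2 * n_probes}"
        )
    top = profile.probes[:n_probes]
    bottom = profile.probes[-n_probes:]
    up = {profile.probe_to_gene[p] for p in top if p in profile.probe_to_gene}
    down = {profile.probe_to_gene[p] for p in bottom if p in profile.probe_to_gene}
    both = up & down
    if both:
        logger.warning(
            "top_bottom_genes: %d gene(s) in both directions removed: %s",
            len(both),
            ", ".join(sorted(both)[:10]),
        )
    return up - both, down - both


def infer_tfs(
    collection: Mapping[str, set[str]],
    regulated: set[str],
    alpha: float = 0.05,
    direction: str = "up",
    universe: set[str] | None = None,
) -> list[TFEnrichmentResult]:
    """Upper-tail hypergeometric over-representation of *regulated* per TF.

    The universe defaults to the union of all target genes in *collection*;
    regulated genes outside the universe are excluded before testing.  Results
    with p < *alpha* are returned sorted by (p, TF symbol).
    """
    if not collection:
        raise ValueError("TF target collection must be non-empty")
    if universe is None:
        universe = set().union(*collection.values())
    N = len(universe)
    reg = set(regulated) & universe
    if not reg:
        logger.warning("infer_tfs: no regulated gene maps into the target universe")
        return []
    n = len(reg)
    results = []
    for tf in sorted(collection):
        targets = collection[tf] & universe
        K = len(targets)
        k = len(targets & reg)
        # P(X >= k); k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, N, K, n))
        if p < alpha:
            results.append(TFEnrichmentResult(tf, direction, k, K, n, N, p))
    results.sort(key=lambda r: (r.p_value, r.tf))
    return results
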