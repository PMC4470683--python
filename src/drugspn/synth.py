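"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates every input the construction and evaluation steps
consume, with planted ground truth for recovery experiments:

* a scale-free background network (preferential attachment) carrying a
  planted signaling cascade — an upstream block wired through a relay block
  to a transcription-factor block;
* TF target sets whose planted members are over-represented among the
  top/bottom probes of a ranked expression profile;
* a SNP association table in which planted pathway genes draw p-values from
  a Beta(0.1, 1) (heavy mass near zero) against a Uniform(0, 1) background,
  plus BED-like gene models laid out so the 20 kb windows never overlap;
* a random-tree ontology per GO domain with leaf-level gene annotations.

Everything is deterministic under the configured RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import netio, weighting
from .tf_infer import RankedExpressionProfile

__all__ = ["FixtureConfig", "FixtureBundle", "make_fixture", "write_fixture"]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic world; defaults are the study conditions.

    The planted cascade connects every upstream-block gene to the TF block
    through the relay block, with ``cascade_density`` edges from each member
    to the next block.  ``enrichment_strength`` is the fraction of a planted
    TF's target set inserted among the regulated probes; 0 disables planting
    (a pure null for calibration).  ``snp_signal_fraction`` is the share of
    cascade genes whose best SNP is drawn from the low-p distribution.
    """

    n_background: int = 300
    attachment: int = 2  # preferential-attachment edges per new node
    n_upstream: int = 8
    n_relay: int = 6
    n_tf: int = 6
    cascade_density: int = 3
    n_decoy_tfs: int = 19
    target_pool_size: int = 2000
    target_set_size: int = 40
    enrichment_strength: float = 0.4
    n_probes: int = 400
    n_top: int = 100
    snps_per_gene: int = 4
    snp_signal_fraction: float = 0.9
    gene_length: int = 10_000
    gene_spacing: int = 100_000
    n_chromosomes: int = 5
    ontology_depth: int = 4
    ontology_branching: int = 3
    terms_per_gene: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_upstream + self.n_relay + self.n_tf > self.n_background:
            raise ValueError("planted cascade larger than the background network")
        if not (0.0 <= self.enrichment_strength <= 1.0):
            raise ValueError("enrichment_strength must lie in [0, 1]")
        if not (0.0 <= self.snp_signal_fraction <= 1.0):
            raise ValueError("snp_signal_fraction must lie in [0, 1]")
        for name in ("n_background", "n_upstream", "n_relay", "n_tf", "n_probes", "n_top"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FixtureBundle:
    """The generated world plus its ground truth."""

    config: FixtureConfig
    network: nx.Graph
    upstream: set[str]
    downstream: set[str]  # planted TFs, the drug's inferred downstream genes
    tf_targets: dict[str, set[str]]
    profile: RankedExpressionProfile
    snps: pd.DataFrame
    gene_models: pd.DataFrame
    ontology: weighting.OntologyDAG
    annotations: dict[str, set[str]]
    relay_nodes: set[str]
    planted_tfs_up: set[str]
    planted_tfs_down: set[str]
    planted_associated: set[str]

    @property
    def planted_tfs(self) -> set[str]:
        return self.planted_tfs_up | self.planted_tfs_down


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _make_background(cfg: FixtureConfig, rng: np.random.Generator) -> nx.Graph:
    g = nx.barabasi_albert_graph(cfg.n_background, cfg.attachment, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})


def _plant_cascade(
    net: nx.Graph, cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[set[str], set[str], set[str]]:
    """Wire upstream -> relay -> TF blocks over randomly chosen nodes."""
    picks = rng.choice(cfg.n_background, size=cfg.n_upstream + cfg.n_relay + cfg.n_tf, replace=False)
    names = [_gene_name(int(i)) for i in picks]
    upstream = set(names[: cfg.n_upstream])
    relays = set(names[cfg.n_upstream : cfg.n_upstream + cfg.n_relay])
    tfs = set(names[cfg.n_upstream + cfg.n_relay :])
    relay_list = sorted(relays)
    tf_list = sorted(tfs)
    d = cfg.cascade_density
    for u in sorted(upstream):
        for r in rng.choice(len(relay_list), size=min(d, len(relay_list)), replace=False):
            net.add_edge(u, relay_list[int(r)])
    for r in relay_list:
        for t in rng.choice(len(tf_list), size=min(d, len(tf_list)), replace=False):
            net.add_edge(r, tf_list[int(t)])
    return upstream, relays, tfs


def _make_tf_targets(
    cfg: FixtureConfig, planted_tfs: list[str], rng: np.random.Generator
) -> dict[str, set[str]]:
    pool = [f"T{i:05d}" for i in range(cfg.target_pool_size)]
    targets: dict[str, set[str]] = {}
    for tf in planted_tfs:
        pick = rng.choice(cfg.target_pool_size, size=cfg.target_set_size, replace=False)
        targets[tf] = {pool[int(i)] for i in pick}
    for j in range(cfg.n_decoy_tfs):
        pick = rng.choice(cfg.target_pool_size, size=cfg.target_set_size, replace=False)
        targets[f"DECOY_TF{j:03d}"] = {pool[int(i)] for i in pick}
    return targets


def _make_profile(
    cfg: FixtureConfig,
    tf_targets: dict[str, set[str]],
    tfs_up: list[str],
    tfs_down: list[str],
    rng: np.random.Generator,
) -> RankedExpressionProfile:
    """Ranked probe list with planted targets in the top/bottom blocks."""
    universe = sorted(set().union(*tf_targets.values()))
    n_plant = int(round(cfg.enrichment_strength * cfg.target_set_size))

    def planted_genes(tfs: list[str]) -> list[str]:
        out: list[str] = []
        for tf in tfs:
            tgts = sorted(tf_targets[tf])
            pick = rng.choice(len(tgts), size=min(n_plant, len(tgts)), replace=False)
            out.extend(tgts[int(i)] for i in pick)
        return sorted(set(out))

    top_genes = planted_genes(tfs_up)[: cfg.n_top]
    bottom_genes = [g for g in planted_genes(tfs_down) if g not in top_genes][: cfg.n_top]

    probes = [f"P{i:05d}" for i in range(cfg.n_probes)]
    # filler genes drawn from the target universe keep every probe mappable
    filler = [universe[int(i)] for i in rng.integers(len(universe), size=cfg.n_probes)]
    genes = list(filler)
    genes[: len(top_genes)] = top_genes
    if bottom_genes:
        genes[-len(bottom_genes) :] = bottom_genes
    # middle probes must not leak planted genes into the regulated blocks
    planted = set(top_genes) | set(bottom_genes)
    safe = sorted(set(universe) - planted)
    for i in range(cfg.n_top, cfg.n_probes - cfg.n_top):
        if genes[i] in planted:
            genes[i] = safe[int(rng.integers(len(safe)))]
    scores = np.sort(rng.normal(size=cfg.n_probes))[::-1]
    mapping = dict(zip(probes, genes))
    return RankedExpressionProfile(probes, scores.tolist(), mapping)


def _make_gwas(
    cfg: FixtureConfig,
    genes: list[str],
    planted: set[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    models = []
    per_chrom = int(np.ceil(len(genes) / cfg.n_chromosomes))
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * cfg.gene_spacing + 50_000
        models.append({"chrom": chrom, "start": start, "end": start + cfg.gene_length, "gene": gene})
    gene_models = pd.DataFrame(models)

    snp_rows = []
    truly_assoc: set[str] = set()
    sid = 0
    for row in gene_models.itertuples(index=False):
        signal = row.gene in planted and rng.random() < cfg.snp_signal_fraction
        if signal:
            truly_assoc.add(row.gene)
        for _ in range(cfg.snps_per_gene):
            pos = int(rng.integers(row.start, row.end))
            p = float(rng.beta(0.1, 1.0)) if signal else float(rng.uniform())
            snp_rows.append({"snp": f"rs{sid:06d}", "chrom": row.chrom, "pos": pos, "p": max(p, 1e-300)})
            sid += 1
    return pd.DataFrame(snp_rows), gene_models, truly_assoc


def _make_ontology(
    cfg: FixtureConfig, genes: list[str], rng: np.random.Generator
) -> tuple[weighting.OntologyDAG, dict[str, set[str]]]:
    parents: dict[str, set[tuple[str, str]]] = {}
    domain: dict[str, str] = {}
    leaves: dict[str, list[str]] = {}
    for dom in weighting.DOMAINS:
        root = f"{dom}:0"
        parents[root] = set()
        domain[root] = dom
        level = [root]
        tid = 1
        for depth in range(cfg.ontology_depth):
            nxt = []
            for parent in level:
                for _ in range(cfg.ontology_branching):
                    term = f"{dom}:{tid}"
                    tid += 1
                    rel = "is_a" if rng.random() < 0.8 else "part_of"
                    parents[term] = {(parent, rel)}
                    domain[term] = dom
                    nxt.append(term)
            level = nxt
        leaves[dom] = level
    dag = weighting.OntologyDAG(parents, domain)
    annotations: dict[str, set[str]] = {}
    for gene in genes:
        terms: set[str] = set()
        for dom in weighting.DOMAINS:
            pool = leaves[dom]
            for _ in range(cfg.terms_per_gene):
                terms.add(pool[int(rng.integers(len(pool)))])
        annotations[gene] = terms
    return dag, annotations


def make_fixture(config: FixtureConfig = FixtureConfig()) -> FixtureBundle:
    """Generate the full synthetic bundle (deterministic per config seed)."""
    rng = np.random.default_rng(config.seed)
    net = _make_background(config, rng)
    upstream, relays, tf_block = _plant_cascade(net, config, rng)

    tf_list = sorted(tf_block)
    half = len(tf_list) // 2
    tfs_up = tf_list[:half] if half else []
    tfs_down = tf_list[half:]
    tf_targets = _make_tf_targets(config, tf_list, rng)
    profile = _make_profile(config, tf_targets, tfs_up, tfs_down, rng)

    cascade = upstream | relays | tf_block
    snps, gene_models, truly_assoc = _make_gwas(config, sorted(net.nodes), cascade, rng)
    dag, annotations = _make_ontology(config, sorted(net.nodes), rng)

    return FixtureBundle(
        config=config,
        network=net,
        upstream=upstream,
        downstream=tf_block,
        tf_targets=tf_targets,
        profile=profile,
        snps=snps,
        gene_models=gene_models,
        ontology=dag,
        annotations=annotations,
        relay_nodes=relays,
        planted_tfs_up=set(tfs_up),
        planted_tfs_down=set(tfs_down),
        planted_associated=truly_assoc,
    )


def write_fixture(bundle: FixtureBundle, outdir) -> dict[str, str]:
    """Write every format the pipeline reads; returns the file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    path = out / "network.tsv"
    netio.write_edge_list(bundle.network, path)
    files["network"] = str(path)

    for name, genes in (("upstream", bundle.upstream), ("downstream", bundle.downstream)):
        path = out / f"{name}_genes.txt"
        path.write_text("".join(f"{g}\n" for g in sorted(genes)))
        files[name] = str(path)

    path = out / "tf_targets.gmt"
    netio.write_gene_sets(bundle.tf_targets, path, description="synthetic")
    files["tf_targets"] = str(path)

    path = out / "profile.tsv"
    with open(path, "wt") as fh:
        for probe, score in zip(bundle.profile.probes, bundle.profile.scores):
            fh.write(f"{probe}\t{score:.6f}\n")
    files["profile"] = str(path)

    path = out / "probe_map.tsv"
    with open(path, "wt") as fh:
        for probe in bundle.profile.probes:
            fh.write(f"{probe}\t{bundle.profile.probe_to_gene[probe]}\n")
    files["probe_map"] = str(path)

    path = out / "snps.tsv"
    bundle.snps.to_csv(path, sep="\t", header=False, index=False)
    files["snps"] = str(path)

    path = out / "gene_models.tsv"
    bundle.gene_models.to_csv(path, sep="\t", header=False, index=False)
    files["gene_models"] = str(path)

    path = out / "ontology.tsv"
    with open(path, "wt") as fh:
        for term in sorted(bundle.ontology.parents):
            links = bundle.ontology.parents[term]
            if not links:
                fh.write(f"{term}\t-\tis_a\t{bundle.ontology.domain[term]}\n")
            for parent, rel in sorted(links):
                fh.write(f"{term}\t{parent}\t{rel}\t{bundle.ontology.domain[term]}\n")
    files["ontology"] = str(path)

    path = out / "annotations.tsv"
    with open(path, "wt") as fh:
        for gene in sorted(bundle.annotations):
            for term in sorted(bundle.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
    files["annotations"] = str(path)

    path = out / "ground_truth.txt"
    with open(path, "wt") as fh:
        fh.write("# relay\n")
        fh.writelines(f"{g}\n" for g in sorted(bundle.relay_nodes))
        fh.write("# planted_tfs\n")
        fh.writelines(f"{g}\n" for g in sorted(bundle.planted_tfs))
        fh.write("# planted_associated\n")
        fh.writelines(f"{g}\n" for g in sorted(bundle.planted_associated))
    files["ground_truth"] = str(path)
    return files
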