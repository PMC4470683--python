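# Methods

This note documents the models implemented in `drugspn`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Background network

The background is a simple undirected graph over gene symbols.  Interaction
records are merged with duplicate pairs collapsed regardless of orientation
and self-loops dropped; records flagged as arising from co-membership in a
protein complex can be excluded, since complex co-membership carries no
signal-flow information.  Directionality from source databases is discarded
deliberately: every downstream analysis (degree, hubs, clique percolation,
the walks) is orientation-free.  Symbols are case-sensitive and
whitespace-trimmed; no alias resolution is attempted — callers supply
harmonized identifiers.

## Functional node weights

Each node *i* is weighted by its Gene Ontology functional similarity to the
drug's upstream set.  Per domain *k* ∈ {MF, BP, CC},
`Score_i(k) = Σ_j sim(i, j) / n` over the *n* upstream genes *j* with a
computable similarity, and the final weight is the mean over the *N* domains
with a score: `Ŝ_i = Σ_k Score_i(k) / N`.  The term-level measure is the
Wang graph-based similarity — semantic contributions propagated down the DAG
with multiplicative factors 0.8 (`is_a`) and 0.6 (`part_of`), compared
through shared ancestors — aggregated to gene level by best-match average.
Wang was chosen because it needs no external information-content corpus; the
measure is a pluggable callable, so an IC-based alternative can be swapped
in.  A node that is itself an upstream gene contributes its self-similarity
of 1.0 to its own mean (the sum runs over upstream genes with existing
scores, with no self-exclusion).  When weights feed the walk, missing
weights are replaced by the minimum observed positive weight — no node is
made unreachable by missing annotation — and the substitution count is
logged.

## Downstream TF inference

The ranked expression profile orders probes by a precomputed rank score
(ties broken by probe id).  The top and bottom `n_probes = 100` probes map
to up-/down-regulated gene sets; probes without a gene mapping are dropped
after selection, and a gene landing in both sets is removed from both (its
direction is ambiguous) with a logged warning.  Each TF target set is tested
by the exact upper-tail hypergeometric against the universe of all target
genes in the supplied collection; the universe is an explicit argument so a
whole-genome background can be substituted.  No multiple-testing correction
is applied at this stage — the selection is the nominal p < 0.05, matching
how such TF screens are conventionally run; `evaluate.bh_adjust` is
available when correction is wanted.  Up and down lists are tested
independently, so a TF can legitimately appear in both directions.

## Longitudinal movement (restart walk + dual nulls)

The walk iterates `p ← (1 − r)·Wp + r·p₀` to an L1 tolerance of 1e-10,
where `W` is the column-stochastic transpose of the row-normalized
transition matrix and `p₀` is uniform over the mapped seeds.  The restart
probability defaults to `r = 0.5` with a uniform restart distribution — the
natural reading of giving every seed an equal starting probability of 0.5.
In `node_weighted` mode the step probability *i → j* is proportional to the
functional weight of *j* among *i*'s neighbors; rows whose neighbor weights
vanish fall back to uniform with a warning, and isolated nodes self-absorb.

Significance is empirical with the add-one correction,
`p = (1 + #{null ≥ observed}) / (perms + 1)`:

* **global** null — seed sets of equal size drawn uniformly from all nodes;
* **local** null — degree-matched draws: each real seed is replaced by a
  random node from its degree bin (equal-frequency bins, default 10, with
  identical degrees sharing a bin; a seed alone in its bin maps to itself,
  logged).

These are the two standard nulls for propagation scores — "higher than any
random seeding" and "higher than degree alone explains".  A node joins the
expanded set when both p-values fall below 0.05; mapped seeds are always
retained.  All permutation runs are propagated as one matrix, so 1000
permutations on a few-hundred-node network take well under a second, and
results are bitwise reproducible for a fixed RNG seed.

A calibration caveat worth stating: under a null with no planted structure,
each node's empirical p-value is Uniform by exchangeability, so with
hundreds of nodes the dual filter still admits a small number of non-seed
nodes in most runs (the measured per-node null admission rate is ≈ 0.015,
comfortably below the nominal 0.05).  "The expansion returns exactly the
seeds" is therefore not a property the construction can promise run-wise —
type-I control here is a per-node rate, not familywise.

## Lateral movement (bounded K-walks)

For each start seed with the remaining seeds absorbing, the expected number
of passages over a directed edge within `L_max` steps is
`passage(i→j) = visits(i)·T(i,j)` with `visits(i) = Σ_{t<L_max} α_t(i)`,
where `α_t` is the unabsorbed occupancy — an exact dynamic program, no
sampling.  Per-start tables are *averaged* over all seeds (relevance is per
walk, symmetric in seed ordering); `L_max` defaults to 50 steps, ample for
absorption on networks of the scale the method targets.  Undirected edge
relevance is the sum of the two directions.

Subnetwork extraction scans candidate thresholds at the distinct relevance
values in descending order and keeps the largest threshold maximizing the
number of seed pairs connected in the retained graph (ties toward fewer
edges, i.e. the first maximum encountered).  The retained graph is
restricted to components containing a seed; seeds that connect to nothing
stay as singletons with a warning.  The objective is a pluggable callable
because "maximum score" admits several readings; seed-pair connectivity
reproduces the intended behavior — the smallest relevant subnetwork that
still connects the seeds.  The lateral step reuses the longitudinal
transition matrix, keeping the two movements consistent.

## Pipeline and provenance

Exactly one longitudinal and one lateral pass per side, no iteration.  The
lateral step seeds on the *entire* longitudinal set of its side, not only on
the original drug genes, so linkers can chain through first-pass
recruits.  Side networks are the background subgraphs induced on the
extracted node sets; the merged network is their node and edge union (an
`induced_union` variant is exposed as a flag), bridge nodes the node
intersection.  Provenance labels follow precedence seed > bridge > extended
> novel; the underlying sets are all retained, so the labeling is purely
presentational.  The two sides use distinct RNG substreams derived from the
run seed (2s and 2s+1), making the pipeline deterministic end to end.

## Evaluation

* **Gene-level GWAS association**: minimum SNP p over
  `[start − W, end + W)` on the gene's chromosome, with 0-based half-open
  gene models, a closed lower and open upper bound, and `W = 20 kb`; a gene
  is *related* when this minimum is < 0.05.  The bound convention had to be
  fixed somewhere; it is stated here and tested at the exact boundary.
* **Enrichment**: exact upper-tail hypergeometric, summed in log space so
  tails far below the double-precision survival function remain accurate;
  backgrounds (genome, background network, genotyped genes) are explicit
  arguments.  Benjamini–Hochberg step-up for batched tests.
* **Category abundance**: `Z = (x − u)/σ` with the *population* standard
  deviation (`ddof=0`, configurable) — the plain formula carries no sample
  correction; categories with Z > 0 are flagged.
* **Hubs**: degree strictly greater than the cutoff.  The
  distribution-derived automatic cutoff of the original hub heuristic is
  under-specified, so an explicit cutoff and an empirical-CDF quantile
  strategy are both provided.
* **Modules**: 3-clique percolation (maximal cliques ≥ k chained by
  (k−1)-node overlap), delegated to networkx and cross-checked in the test
  suite against a brute-force clique enumeration with union-find.
  Community order is deterministic (size descending, then member tuple).

## Synthetic fixtures

`synth.make_fixture` generates, deterministically per seed: a 300-node
preferential-attachment background (attachment 2, giving the right-skewed
degree distribution characteristic of signaling networks); a planted cascade
of 8 upstream genes wired through 6 relays to 6 TFs with 3 cross-block edges
per member; 25 TF target sets of 40 genes over a 2000-gene pool (6 planted,
19 decoys); a 400-probe ranked profile in which 40% of each planted TF's
targets occupy the top (up-TFs) or bottom (down-TFs) 100 probes; 4 SNPs per
gene with planted-cascade genes drawing p ~ Beta(0.1, 1) (90% of them) and
background genes p ~ Uniform(0, 1), on non-overlapping 10 kb gene models
spaced 100 kb apart; and a random-tree ontology per GO domain with leaf
annotations.  Setting the enrichment strength to 0 or the cascade density
to 0 yields pure nulls for calibration.

What the generator does *not* emulate: real rank statistics of expression
platforms, linkage disequilibrium between SNPs, correlated TF target sets,
annotation depth heterogeneity, or the density profile of curated
interactomes.  Passing recovery tests therefore demonstrates that the
implementation recovers the structure it models — planted linkers and
active TFs at the stated rates — not that the method's power transfers
quantitatively to any particular real dataset.

Problem sizes used in the shipped experiments (a deliberate choice to keep
them comfortably re-runnable anywhere): recovery averaged over 20 fixture
seeds at 1000 permutations, null calibration over 12 seeds, Monte-Carlo
walk oracles at 10⁶ walks, exhaustive hypergeometric enumeration to N = 12,
clique-percolation cross-checks over 100 random graphs of up to 12 nodes.

## Known limitations

* The construction is evaluated against its own synthetic world; the
  published 477-node metformin network itself is not reconstructible
  without licensed interaction and TF databases and the original expression
  profiles, and its printed enrichment p-values are not consistent with the
  printed contingency counts under any standard tail convention (the exact
  values at those counts are computed and reported by
  `scripts/acceptance.py`).
* Empirical p-values are resolution-limited at 1/(perms + 1); with the
  default 1000 permutations the smallest attainable p is ≈ 0.001.
* Degree-matched permutation bins are equal-frequency; on very small or
  very homogeneous networks a seed can dominate its own bin, making the
  local null conservative (logged when a seed's bin is a singleton).
* The k-clique percolation step enumerates maximal cliques and is
  exponential in the worst case; it is intended for drug-specific networks
  of hundreds of nodes, not for the full background interactome.
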