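# Methods

## Haplotype representation and filtering

A haplotype is a set of variant calls against the rCRS coordinate system
(1-based positions 1..16,569) over a declared closed range, by default the
HVS-I segment 16,051–16,400. Identity to the reference over the range is the
empty set. Tokens follow the EMPOP convention: `16172C` (substitution),
`16183.1C` (insertion with sub-index), `16189d`/`16189del` (deletion), and
IUPAC ambiguity letters (`16093Y`) read as heteroplasmic calls. Calls outside
the declared range are rejected at parse time with the offending tokens
named; this is why inputs that score position 16519 must declare a range
extending to the control-region end (e.g. 16051–16569) — 16519 lies beyond
HVS-I proper.

The default pre-phylogenetic filter drops 16182C and 16183C (poly-C tract
artefacts; only the C calls, a literal reading of the conventional rule —
how a hypothetical non-C call at these positions should be treated is not
settled, so it is kept), position 16519 for any allele, and all indels and
heteroplasmies. Filtering is idempotent and never mutates its input.

The rCRS sequence itself is not bundled. Substitution-vs-reference
validation and FASTA scoring run against a user-supplied reference;
`synthetic_reference()` provides a deterministic pseudo-random stand-in
(clearly not the real rCRS) so the FASTA path and simulator are
self-contained. The bundled haplogroup motif table covers only the major
African lineages (U6/U6a, M1, L1b, L2, L3) and is illustrative; serious
classification should supply a fuller, curated hierarchy.

## Frequency and diversity statistics

Percentages are 100·count/n rounded half-up to two decimals (matching how
published tables are rendered; one-decimal prose values are roundings of
the same quantities). The derived "African lineages" row sums the U6, M1
and L major rows only, so nested sub-haplogroup rows are not double
counted.

MNPD averages, over all unordered pairs, the number of positions whose
state differs — including presence/absence against the reference, and
counting two different derived alleles at one position once.

The differentiation statistic is a pairwise-difference (Φ_ST-like) F_ST:
(mean between-group difference − mean within-group difference) / mean
between, with within-group pairs pooled across both groups. Negative values
are reported as-is; an all-identical input returns F_ST = 0 with p = 1. The
permutation p-value counts label assignments with F_ST at least the
observed value; when C(n, n₁) ≤ n_perm all splits are enumerated (the
p-value is then exact and seed-independent), otherwise n_perm seeded random
permutations are drawn with the observed labelling included, so p > 0. No
published F_ST value is a reproduction target: the underlying
per-individual datasets and estimator choices behind published numbers are
not available, so this statistic is a documented functional analogue.

## Median-joining networks

The network treats each varied position as a binary character (derived
state present/absent); recurrent mutation appears as the same position
labelling several edges. Construction iterates: (1) feasible links = the
ε-relaxed minimum spanning network, computed from the minimax-path
characterisation (an edge is in some MST iff its weight equals the heaviest
edge on the MST path between its endpoints; ε admits edges within ε of that
threshold); (2) candidate medians are majority-consensus vectors of triples
— all triples when the node set has ≤ 30 members, otherwise Bandelt-style
connected triples; (3) the candidate (or, where no single candidate helps
and the candidate set is small, the candidate *pair*) that most reduces the
spanning cost is added. The pair lookahead exists because a greedy single
addition can land in a local optimum that a coordinated pair avoids; it is
bounded (≤ 60 candidates) so large runs stay cheap. After convergence,
inferred medians whose removal does not increase the spanning cost are
pruned in deterministic order.

The final edge set is the MSN over the final node set **union** the MSN
over observed nodes alone. The union matters: a chain of single-step edges
through medians can otherwise displace an equally parsimonious direct
alternative link between observed nodes, and the network is meant to
display all shortest alternative connections. With ε = 0 the result
therefore contains the union of all MSTs of the observed nodes, and on
small instances its spanning cost matches exhaustive Steiner search over
median vectors (both properties are tested).

Ties everywhere (link order, candidate choice) break lexicographically by
(weight, sorted site set, node id) for run-to-run determinism. Position
weights default to 1; a weight table can up-weight conserved positions.
Only median-joining is implemented (no reduced-median variant): downstream
founder analysis consumes founder nodes, not the network flavour.

## ρ dating

ρ = Σ_b (n_b/n)·m_b (equivalently the mean root-to-tip mutation count) and
σ² = Σ_b (n_b/n)²·m_b, treating branch counts as independent Poisson
observations. Ages are ρ·r with r years per mutation; the 95% interval is
the normal approximation age ± 1.96·σ·r with the lower bound floored at
zero (negative ages are not meaningful and published intervals are rendered
that way). Bundled clocks: whole-mtDNA 3,624, synonymous 7,884, HVS-I
16,677, and 2,643 y/mutation for complete-mtDNA founder analysis (a central
value between young- and old-founder rates, since the allocation machinery
needs a single rate). These calibrations already embed a purifying-
selection correction; no additional rate adjustment is applied here, and no
maximum-likelihood (e.g. HKY85+Γ) dating is provided. Site-class filtering
(for the synonymous clock) requires branches annotated with explicit
mutation positions and a complete position→class table; unclassified
positions are reported, not guessed.

Cluster trees come either from Newick with non-negative integer branch
lengths (mutation counts) or from founder clusters, where each sink
sample's shortest network path to the founder (ties: fewest total
mutations, then lexicographic) becomes its root path. Per-leaf chains are
not merged on shared prefixes; ρ and σ depend only on per-leaf path sums
and per-branch leaf counts, which the chain construction preserves, and a
reticulated network offers no canonical shared-prefix tree anyway.

## Founder analysis

For each sink sample, the nearest node (edge-count distance) carrying
source-population membership is its founder. Source-derived branches of a
founder are counted as the connected components, after removing the founder
node, that contain at least one source sample and no sink samples; f1
requires ≥ 1 such branch, f2 ≥ 2, f0 none (so f2 ⊆ f1 ⊆ f0 by
construction). Sink samples with no reachable source-bearing node are
excluded with a logged warning.

Migration-time allocation follows the Poisson machinery stated in the
README: per-founder posteriors over a 0–60 ky grid in 200-y steps (0–50 ky
is conventional for sub-Saharan L-style scans; the grid is configurable),
with the t = 0 convention Poisson(M; 0) = 1 iff M = 0. The prior over
candidate times is uniform — the allocation literature does not force a
particular prior and uniform is the transparent default. Aggregation
weights founders by sink descendant counts, matching the "distribution of
lineages" reading; with few private mutations per founder the aggregate
piles mass near t = 0 (the recent-peak phenomenon familiar from published
scans), so meaningful mode recovery needs substantial lineage counts (see
benchmark sizes below).

Reciprocal runs execute both directions on one network. The direction whose
source region shows higher private diversity (Σ n_i·ρ_i measured when that
region is treated as the sink) is flagged as the supported origin;
relative differences under 10% are called ambiguous (a conventional band
chosen a priori). The reversed direction's scan mode is expected to be
biased old, because diversity retained at home but never transported is
mistaken for post-migration accumulation.

## Synthetic data

The generator produces exactly the structure the founder machinery assumes.
The source genealogy is a serial-sample (heterochronous) Kingman coalescent
with constant size: present-day source samples are tips at t = 0 and each
migration event's founder lineages are ancient tips at the event time,
coalescing with the rest of the source genealogy above it. The effective
size is scaled so the expected TMRCA of the present-day sample equals
`source_tmrca_years` (N = tmrca / (2(1 − 1/n))). Mutations fall as Poisson
per branch (branch length / r) over a finite site array; 5% of sites
default to a 10× rate (hotspots), and repeat hits toggle the derived state,
producing the homoplasy and network reticulation real control-region data
show. Each founder lineage expands in the sink as a star: every sink
descendant adds Poisson(t/r) private mutations, so E[sink-private ρ·r] = t
exactly — the identity ρ dating relies on. Founder lineages also leave
`source_descendants_per_founder` (default 3) present-day source
descendants, star-wise from the founder tip: without them the founder
haplotype would be absent from the sampled source and network founder
identification could not work even in principle; with them the founder type
usually persists unchanged in the source and its mutated descendants are
precisely the source-derived branches the f1/f2 criteria require.

Defaults: 350 sites, HVS-I clock, source TMRCA 130 ky (a deep sub-Saharan
L-like clade; at HVS-I resolution a ~35-ky clade carries only ~2 mutations
root-to-tip, so distinct founder lineages would share haplotypes and no
method could separate them), one migration at 8 ky with 10 founders.
Everything is driven by a single mandatory seed; outputs are byte-identical
across runs. The truth record lists each sink sample's founding event,
founder lineage and private mutation draws, and `founders_from_truth()`
rebuilds exact founder clusters from it so dating/allocation can be tested
in isolation from network-based identification.

What the simulator does **not** emulate: population growth or structure
within source or sink, coalescence among sink lineages after founding
(star expansion is exact for the ρ model but suppresses shared sink-private
branches), selection, back-migration, and sequencing error. Passing
benchmarks therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to real-data violations of them.

## Benchmark problem sizes and numerical choices

- Single-epoch scan recovery: 8 ky migration, 50 founder lineages, HVS-I
  clock, 12,000 sink lineages, 100 seeded replicates; the aggregate-mode
  criterion is one 200-y grid step. The lineage count comes from a power
  argument: the aggregate is a mixture whose mode has Monte-Carlo width
  ~ t/√(M̄ per founder), so matching the grid step at the HVS-I clock needs
  per-founder private mutation counts near 10², i.e. ~240 descendants per
  founder.
- Two-epoch partition: 0.5 ky and 8 ky events, 25 founders each, 200 sink
  lineages, tolerance ±0.10 on the recovered fractions, 100 replicates.
- Reciprocal directionality: 6 founders at 8 ky, 40 source + 60 sink
  samples, 4 source descendants per founder; expected ≥95% correct source
  calls and a strictly older mean reversed-direction mode.
- Posterior normalisation happens in log space (max-subtracted) to avoid
  underflow on long grids; aggregate mass sums to 1 within 1e-12.
- All tie-breaks (network links, founder candidates, path choices) are
  lexicographic and logged at DEBUG level.

## Known limitations

- Haplogroup assignment is motif-containment against a user-extensible
  table, not a full PhyloTree caller.
- The founder's private tree is reconstructed from shortest network paths;
  in heavily reticulated regions this is one defensible choice among
  several, and alternative paths with equal length are resolved by the
  deterministic tie-break rather than averaged.
- Published founder-analysis percentages from literature-compiled datasets
  (epoch concordances across sinks, haplogroup-specific partitions) are not
  reproduction targets: the underlying compiled per-sample datasets are not
  redistributable, so the package demonstrates the machinery on synthetic
  data with known truth instead.
- The ε > 0 network relaxation is exposed but defaults to 0; published
  network figures rarely state their ε and weight settings.
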