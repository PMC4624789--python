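# mitofounder

Maternal-lineage phylogeography from mitochondrial DNA haplotypes: parse and
filter control-region (HVS-I) or complete-mitogenome variant data, build
median-joining haplotype networks, summarise haplogroup frequencies and
diversity, date clades with the ρ statistic, and run source–sink **founder
analysis** with probabilistic migration-time allocation. A ground-truth
source–sink simulator makes every stage verifiable end to end.

The package is aimed at population geneticists studying human (or other
non-recombining, maternally inherited) mtDNA variation — e.g. tracing African
maternal lineages (U6, M1, L) across the Mediterranean basin — and at anyone
who needs a tested, scriptable founder-analysis implementation.

## The method

**Haplotypes** are sets of variant calls against the rCRS coordinate system
(EMPOP-style tokens such as `16172C 16219G`), restricted by default to HVS-I
positions 16,051–16,400. Before analysis, the hypermutable calls 16182C,
16183C and 16519 together with indels and heteroplasmies are dropped.

**Median-joining networks** connect observed haplotypes through a minimum
spanning network (union of all minimum spanning trees under weighted Hamming
distance) augmented with inferred median (majority-consensus) haplotypes that
reduce the spanning cost, with obsolete medians pruned.

**ρ dating.** For a clade with n sampled tips, ρ is the mean number of
mutations from root to tip, ρ = Σ_b (n_b/n)·m_b over branches b. Its
standard error follows the branch-Poisson variance σ² = Σ_b (n_b/n)²·m_b.
Age = ρ·r, where the clock r (years per mutation) is one of the bundled
calibrations: 3,624 y (whole mitogenome), 7,884 y (synonymous only),
16,677 y (HVS-I), 2,643 y (complete-mtDNA founder analysis).

**Founder analysis.** Each sink-population lineage is matched to its nearest
source-bearing network node (its founder). A candidate founder is accepted
under criterion *f1* (*f2*) if it displays at least one (two) derived
branch(es) private to the source — a guard against back-migration and
homoplasy. Each founder cluster's sink-private diversity, with n descendants
and M private mutations, yields a likelihood Poisson(M; n·t/r) at candidate
migration time t; with a uniform prior over a 200-year grid (0–60 ky by
default) the normalised likelihood is the founder's migration-time
posterior, and founders are aggregated weighted by their descendant share.
The same machinery restricted to a fixed epoch set (default 0.5 ky and 8 ky)
partitions lineages between, e.g., historic and early-Holocene migrations.
Reciprocal runs (swapping source and sink) compare private diversity on both
sides to flag the supported direction of migration and expose the old-age
bias of the reversed direction.

## Worked example

```python
import mitofounder as mf

# 1. published haplogroup counts -> percentage table
table = mf.frequency_table(mf.load_andalusia_berber_counts())
print(table.loc[["U6", "M1", "L", "African lineages"],
                [("Huelva", "n"), ("Huelva", "%"),
                 ("Granada", "n"), ("Granada", "%")]])

# 2. simulate a known 8-ky migration, then recover it
cfg = mf.SimConfig(seed=42, n_source_lineages=40, n_sink_samples=60,
                   source_descendants_per_founder=4,
                   migration_events=((8000.0, 6),))
res = mf.simulate_source_sink(cfg)
net = mf.build_mj_network(res.haplotypes)
clusters = mf.identify_founders(net, "Source", "Sink", criterion="f1")
for c in clusters:
    age, (lo, hi) = c.age("hvs1")
    print(f"founder {c.founder_node.node_id}: n={c.n} rho={c.rho():.2f} "
          f"age={age/1000:.1f} ky (95% CI {lo/1000:.1f}-{hi/1000:.1f})")
scan = mf.scan_migration_times(clusters, clock="hvs1")
print(f"aggregate scan mode: {scan.mode():.0f} y")
```

prints

```
                 Huelva        Granada
                      n      %       n     %
haplogroup
U6                   21   7.50       7  1.49
M1                    1   0.36       3  0.64
L                    11   3.93       7  1.49
African lineages     33  11.79      17  3.62

founder H1: n=10 rho=0.70 age=11.7 ky (95% CI 3.0-20.3)
founder H30: n=10 rho=0.30 age=5.0 ky (95% CI 0.0-10.7)
founder H44: n=10 rho=0.30 age=5.0 ky (95% CI 0.0-10.7)
founder H5: n=10 rho=0.60 age=10.0 ky (95% CI 2.0-18.0)
founder H7: n=20 rho=0.50 age=8.3 ky (95% CI 3.2-13.5)
aggregate scan mode: 8000 y
```

The frequency table reproduces the published percentages exactly (Huelva's
African maternal component is 33/280 = 11.79%); the founder analysis of the
simulated dataset dates each founder's sink-private diversity and the
aggregate posterior peaks at the simulated migration time of 8,000 years.

The same stages are available from the shell:

```bash
mitofounder simulate --seed 42 -o sim/
mitofounder founders sim/haplotypes.tsv --source Source --sink Sink \
    --criterion f1 --clock hvs1 --epochs 500,8000 -o fa/
mitofounder freq src/mitofounder/data/andalusia_berber_counts.tsv -o freq/
```

Every output directory receives a `manifest.json` (command, config, input
digests, seed, version); re-running with the same manifest reproduces
stochastic outputs bit-exactly.

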