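"""Source-sink haplotype simulator with a known migration history.

The generator produces the data structure the founder-analysis machinery
assumes: a source population whose lineages descend from a neutral
constant-size coalescent genealogy, discrete migration events that copy a
chosen number of lineages (extant at the event time) into a sink
population, and present-day samples from both.  Mutations fall as a
Poisson process along branches at a configurable clock (years per
mutation) over a finite number of sites; a configurable fraction of
hotspot sites mutates at a multiplied rate, and repeat hits toggle the
derived state (recurrent mutation, the cause of network reticulation).

Each founder lineage expands in the sink as a star genealogy: every sink
descendant sampled today accumulates private mutations over exactly the
time since its founding event, so the expected sink-private rho of a
founder cluster equals the migration time divided by the clock — the
identity the founder-analysis dating machinery relies on.

Every run is fully determined by ``SimConfig.seed``; the returned truth
record lists each sink sample's founding event and founder haplotype, so
pipeline stages can be scored against the exact simulated history.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .haplotype_io import HVS1_RANGE, Haplotype, VariantCall, VariantKind

__all__ = [
    "SimConfig",
    "GenealogyNode",
    "SimResult",
    "simulate_source_genealogy",
    "sprinkle_mutations",
    "simulate_source_sink",
    "founders_from_truth",
]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a source-sink simulation.

    Defaults emulate an HVS-I founder-analysis setting: 350 assayable
    sites, the HVS-I clock of one mutation per 16,677 years, a deep source
    pool coalescing around 130 ky (a sub-Saharan L-like clade, so founder
    haplotypes are mutually distinct at HVS-I resolution), a single
    early-Holocene migration at 8 ky carrying 10 founder lineages, and 5%
    of sites mutating at 10x rate (recurrent-position hotspots).  A
    shallower clade (e.g. 35 ky, U6-like) can be configured but leaves
    founder lineages harder to tell apart from control-region data alone.
    """

    seed: int
    n_source_lineages: int = 100
    n_sink_samples: int = 100
    sequence_length: int = 350
    years_per_mutation: float = 16_677.0
    source_tmrca_years: float = 130_000.0
    migration_events: tuple[tuple[float, int], ...] = ((8_000.0, 10),)
    #: present-day source samples descending from each founder lineage; the
    #: founder haplotype usually persists in the source (enabling shared
    #: founder nodes) and its mutated descendants are the source-derived
    #: branches the f1/f2 criteria look for
    source_descendants_per_founder: int = 3
    hotspot_fraction: float = 0.05
    hotspot_multiplier: float = 10.0
    source_name: str = "Source"
    sink_name: str = "Sink"
    range: tuple[int, int] = HVS1_RANGE

    def __post_init__(self) -> None:
        if self.n_source_lineages < 1 or self.sequence_length < 1:
            raise SimConfigError("counts must be positive")
        if self.n_sink_samples < 0:
            raise SimConfigError("n_sink_samples must be >= 0")
        if self.years_per_mutation <= 0 or self.source_tmrca_years <= 0:
            raise SimConfigError("clock and TMRCA must be positive")
        for t, k in self.migration_events:
            if t >= self.source_tmrca_years:
                raise SimConfigError(
                    f"migration time {t} is not below the source TMRCA "
                    f"{self.source_tmrca_years}"
                )
            if t < 0 or k < 1:
                raise SimConfigError("migration events need t >= 0 and k >= 1")
        if not 0 <= self.hotspot_fraction < 1 or self.hotspot_multiplier < 1:
            raise SimConfigError("invalid hotspot settings")
        if self.source_descendants_per_founder < 0:
            raise SimConfigError("source_descendants_per_founder must be >= 0")
        lo, hi = self.range
        if hi - lo + 1 < self.sequence_length:
            raise SimConfigError("range too short for sequence_length")


@dataclass
class GenealogyNode:
    """Node of a source genealogy; ``time`` is years before present."""

    label: str
    time: float
    children: list["GenealogyNode"] = field(default_factory=list)
    #: mutations on the branch to the parent, as (site_index, time) pairs,
    #: filled in by sprinkle_mutations
    mutations: list[tuple[int, float]] = field(default_factory=list)

    def leaves(self) -> list["GenealogyNode"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def total_branch_length(self) -> float:
        total = 0.0
        for node in self.walk():
            for c in node.children:
                total += node.time - c.time
        return total


def simulate_source_genealogy(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenealogyNode:
    """Neutral constant-size coalescent over the source sample.

    The effective-size scaling is chosen so the expected TMRCA equals
    ``cfg.source_tmrca_years``: for n lineages E[TMRCA] = 2N(1 - 1/n), so
    N = tmrca / (2 (1 - 1/n)).  Single-lineage configs return a trivial
    one-branch tree of depth 0.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_source_lineages
    nodes = [GenealogyNode(label=f"S{i + 1}", time=0.0) for i in range(n)]
    if n == 1:
        return nodes[0]
    scale_n = cfg.source_tmrca_years / (2.0 * (1.0 - 1.0 / n))
    t = 0.0
    active = list(nodes)
    counter = 0
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / scale_n
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        counter += 1
        parent = GenealogyNode(label=f"anc{counter}", time=t)
        parent.children = [active[i], active[j]]
        del active[j]
        active[i] = parent
    return active[0]


def _serial_genealogy(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[GenealogyNode, dict[str, tuple[int, float]]]:
    """Kingman coalescent with the founder lineages as ancient tips.

    Present-day source samples enter at time 0; each migration event
    (t, k) contributes k additional tips at time t — the lineages that
    migrate into the sink.  Going backward, lineages coalesce at rate
    C(k,2)/N between tip-addition times, so founders coalesce naturally
    with the source genealogy above their event time.  Returns the root
    and a map founder-tip label -> (event index, event time).
    """
    n = cfg.n_source_lineages
    scale_n = (
        cfg.source_tmrca_years / (2.0 * (1.0 - 1.0 / n))
        if n > 1
        else cfg.source_tmrca_years / 2.0
    )
    active: list[GenealogyNode] = [
        GenealogyNode(label=f"S{i + 1}", time=0.0) for i in range(n)
    ]
    founder_tips: dict[str, tuple[int, float]] = {}
    pending: list[tuple[float, int, int]] = sorted(
        (t, ev_idx, k) for ev_idx, (t, k) in enumerate(cfg.migration_events)
    )
    t = 0.0
    counter = 0
    fcount = 0
    while len(active) > 1 or pending:
        k = len(active)
        rate = k * (k - 1) / 2.0 / scale_n if k > 1 else 0.0
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if pending and t + dt >= pending[0][0]:
            t_ev, ev_idx, n_new = pending.pop(0)
            t = t_ev
            for _ in range(n_new):
                fcount += 1
                label = f"F{fcount}"
                active.append(GenealogyNode(label=label, time=t_ev))
                founder_tips[label] = (ev_idx, t_ev)
            continue
        t += dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        counter += 1
        parent = GenealogyNode(label=f"anc{counter}", time=t)
        parent.children = [active[i], active[j]]
        del active[j]
        active[i] = parent
    return active[0], founder_tips


def _site_rates(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Relative per-site mutation weights with a hotspot class."""
    rates = np.ones(cfg.sequence_length)
    n_hot = int(round(cfg.hotspot_fraction * cfg.sequence_length))
    if n_hot:
        hot = rng.choice(cfg.sequence_length, size=n_hot, replace=False)
        rates[hot] = cfg.hotspot_multiplier
    return rates


def _draw_mutations(
    n: int, site_probs: np.ndarray, rng: np.random.Generator
) -> list[int]:
    return [int(s) for s in rng.choice(len(site_probs), size=n, p=site_probs)]


def sprinkle_mutations(
    tree: GenealogyNode,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    site_probs: np.ndarray | None = None,
) -> dict[str, frozenset[int]]:
    """Drop Poisson mutations on a genealogy and read off leaf states.

    Per-branch counts are Poisson(branch_length / r); each mutation picks a
    site from the (hotspot-weighted) site distribution and a uniform time
    on its branch, and toggles the derived state.  Returns the derived
    site-index set per leaf label; branch mutations are recorded on the
    tree nodes for downstream use.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if site_probs is None:
        rates = _site_rates(cfg, rng)
        site_probs = rates / rates.sum()
    # mean total rate is preserved: one mutation per r years across the
    # whole sequence, hotspots only reshaping the per-site distribution
    for node in tree.walk():
        for child in node.children:
            length = node.time - child.time
            count = rng.poisson(length / cfg.years_per_mutation)
            sites = _draw_mutations(count, site_probs, rng)
            times = node.time - rng.uniform(0.0, length, size=count) if count else []
            child.mutations = sorted(zip(sites, times), key=lambda st: -st[1])

    states: dict[str, frozenset[int]] = {}

    def descend(node: GenealogyNode, state: frozenset[int]) -> None:
        state = state.symmetric_difference(
            _toggle_multiset(site for site, _ in node.mutations)
        )
        if not node.children:
            states[node.label] = state
        for c in node.children:
            descend(c, state)

    descend(tree, frozenset())
    return states


def _toggle_multiset(sites) -> frozenset[int]:
    """Sites hit an odd number of times (the net toggle set)."""
    counts: dict[int, int] = {}
    for s in sites:
        counts[s] = counts.get(s, 0) + 1
    return frozenset(s for s, c in counts.items() if c % 2)


@dataclass
class SimResult:
    """Simulated dataset plus the ground-truth migration record."""

    config: SimConfig
    haplotypes: list[Haplotype]
    #: per sink sample: event index, event time (years), founder lineage id,
    #: founder site set, number of private mutation draws
    truth: dict[str, dict]
    #: per founder lineage id: event index, event time, founder site set
    founder_lineages: dict[str, dict]

    def truth_json(self) -> str:
        payload = {
            "config": {
                **{
                    k: v
                    for k, v in asdict(self.config).items()
                    if k not in ("migration_events", "range")
                },
                "migration_events": [list(e) for e in self.config.migration_events],
                "range": list(self.config.range),
            },
            "samples": self.truth,
            "founder_lineages": {
                fid: {**rec, "sites": sorted(rec["sites"])}
                for fid, rec in self.founder_lineages.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _sites_to_haplotype(
    sites: frozenset[int],
    cfg: SimConfig,
    alleles: Sequence[str],
    **annotations,
) -> Haplotype:
    lo = cfg.range[0]
    calls = frozenset(
        VariantCall(lo + s, alleles[s], VariantKind.SUBSTITUTION) for s in sites
    )
    return Haplotype(range=cfg.range, variants=calls, **annotations)


def simulate_source_sink(cfg: SimConfig) -> SimResult:
    """Simulate present-day source and sink samples with known history.

    The source genealogy is a serial-sample Kingman coalescent: present-day
    source samples are tips at time 0 and each migration event's founder
    lineages are ancient tips at the event time, coalescing with the rest
    of the source genealogy above it.  Each founder lineage then expands in
    the sink as a star: every sink descendant carries the founder haplotype
    plus Poisson(t/r) private mutations.  Sink samples are allocated
    round-robin over founder lineages (events in time order), so every
    founder lineage receives at least one sample when ``n_sink_samples``
    is at least the total founder count.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_sink_samples > 0 and not cfg.migration_events:
        raise SimConfigError("sink sampling requested but no migration events")
    tree, founder_tips = _serial_genealogy(cfg, rng)
    rates = _site_rates(cfg, rng)
    site_probs = rates / rates.sum()
    leaf_states = sprinkle_mutations(tree, cfg, rng, site_probs=site_probs)
    alleles = [str(b) for b in rng.choice(list("ACGT"), size=cfg.sequence_length)]

    founder_lineages: dict[str, dict] = {}
    founder_order = sorted(founder_tips, key=lambda f: int(f[1:]))
    for fid in founder_order:
        ev_idx, t_ev = founder_tips[fid]
        founder_lineages[fid] = {
            "event": ev_idx,
            "time": t_ev,
            "sites": set(leaf_states[fid]),
        }

    haplotypes: list[Haplotype] = []
    for label in sorted(leaf_states):
        if label in founder_tips:
            continue  # latent migrating lineages, not present-day samples
        haplotypes.append(
            _sites_to_haplotype(
                leaf_states[label],
                cfg,
                alleles,
                sample_id=label,
                population=cfg.source_name,
                region_role="source",
            )
        )

    # present-day source descendants of each founder lineage (star from the
    # founder tip): the founder type persisting and diversifying at home
    for fid in founder_order:
        rec = founder_lineages[fid]
        for j in range(cfg.source_descendants_per_founder):
            n_mut = int(rng.poisson(rec["time"] / cfg.years_per_mutation))
            state = frozenset(rec["sites"]) ^ _toggle_multiset(
                _draw_mutations(n_mut, site_probs, rng)
            )
            haplotypes.append(
                _sites_to_haplotype(
                    state,
                    cfg,
                    alleles,
                    sample_id=f"{fid}s{j + 1}",
                    population=cfg.source_name,
                    region_role="source",
                )
            )

    truth: dict[str, dict] = {}
    for i in range(cfg.n_sink_samples):
        fid = founder_order[i % len(founder_order)]
        rec = founder_lineages[fid]
        t_ev = rec["time"]
        n_mut = int(rng.poisson(t_ev / cfg.years_per_mutation))
        private_sites = _draw_mutations(n_mut, site_probs, rng)
        state = frozenset(rec["sites"]) ^ _toggle_multiset(private_sites)
        sid = f"K{i + 1}"
        haplotypes.append(
            _sites_to_haplotype(
                state,
                cfg,
                alleles,
                sample_id=sid,
                population=cfg.sink_name,
                region_role="sink",
            )
        )
        truth[sid] = {
            "event": rec["event"],
            "time": t_ev,
            "founder": fid,
            "founder_sites": sorted(rec["sites"]),
            "private_mutation_draws": n_mut,
        }
    return SimResult(
        config=cfg, haplotypes=haplotypes, truth=truth, founder_lineages=founder_lineages
    )


def founders_from_truth(result: SimResult) -> list:
    """Exact founder clusters from the simulation's truth record.

    Groups sink samples by their true founder lineage and builds each
    cluster's private tree as a star with the drawn per-sample private
    mutation counts.  Used to test the dating/allocation machinery in
    isolation from network-based founder identification.
    """
    from .founder_analysis import FounderCluster
    from .mj_network import NetworkNode
    from .rho_dating import tree_from_paths

    by_founder: dict[str, list[str]] = {}
    for sid, rec in result.truth.items():
        by_founder.setdefault(rec["founder"], []).append(sid)
    lo = result.config.range[0]
    clusters = []
    for fid in sorted(by_founder):
        samples = sorted(by_founder[fid])
        paths = {
            sid: [result.truth[sid]["private_mutation_draws"]] for sid in samples
        }
        sites = frozenset(lo + s for s in result.founder_lineages[fid]["sites"])
        node = NetworkNode(
            node_id=fid,
            sites=sites,
            samples=(("", result.config.source_name, "source"),),
        )
        clusters.append(
            FounderCluster(
                founder_node=node,
                sink_samples=tuple(samples),
                private_tree=tree_from_paths(paths, root_label=fid),
                source_derived_branches=1,
            )
        )
    return clusters
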