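"""Median-joining networks of mtDNA haplotypes.

The network treats every varied position as a binary character (derived
allele present/absent relative to the reference), which is the standard
representation for HVS-I substitution data; recurrent mutation shows up as
the same position labelling several edges.  Construction follows the
Bandelt median-joining scheme:

1. build the minimum spanning network (the union of all minimum spanning
   trees, relaxed by a tolerance ``epsilon``) over the current node set
   under weighted Hamming distance;
2. for triplets of nodes connected within that network, form the median
   (majority-consensus) haplotype and add any median that lowers the cost
   of spanning the node set;
3. drop inferred nodes that have become obsolete;
4. repeat to a fixpoint.

Nodes are condensed haplotypes: identical variant sets share a node and the
node records its per-population sample composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .haplotype_io import Haplotype, HaplotypeError

__all__ = [
    "NetworkNode",
    "HaploNetwork",
    "condense",
    "build_mj_network",
    "write_edge_list",
    "write_graphml",
]

MAX_MJ_ITERATIONS = 200


class ConvergenceError(RuntimeError):
    """Median-joining failed to reach a fixpoint within the iteration cap."""


@dataclass(frozen=True)
class NetworkNode:
    """A condensed haplotype in the network.

    ``sites`` is the set of positions at which the node carries the derived
    state.  ``samples`` lists the (sample_id, population, role) triples that
    map to this node; empty for inferred median vectors.
    """

    node_id: str
    sites: frozenset[int]
    samples: tuple[tuple[str, str, str], ...] = ()
    inferred: bool = False

    @property
    def multiplicity(self) -> int:
        return len(self.samples)

    def populations(self) -> set[str]:
        return {pop for _, pop, _ in self.samples}

    def roles(self) -> set[str]:
        return {role for _, _, role in self.samples}


@dataclass
class HaploNetwork:
    """Graph of observed and inferred haplotype nodes.

    ``graph`` is an undirected networkx graph whose edges carry
    ``positions`` (the frozenset of differing sites) and ``weight`` (the
    summed per-position weights).
    """

    graph: nx.Graph
    nodes: dict[str, NetworkNode]
    epsilon: float = 0.0
    weights: Mapping[int, float] = field(default_factory=dict)

    def node_for_sample(self, sample_id: str) -> NetworkNode:
        for node in self.nodes.values():
            if any(sid == sample_id for sid, _, _ in node.samples):
                return node
        raise KeyError(sample_id)

    def observed_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if not n.inferred]

    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def condense(haplotypes: Sequence[Haplotype]) -> list[NetworkNode]:
    """Merge identical haplotypes into nodes with multiplicities.

    Identity is judged on the substitution sites (the binary network state);
    haplotypes should be filtered first so indels/heteroplasmies are gone.
    """
    ranges = {h.range for h in haplotypes}
    if len(ranges) > 1:
        raise HaplotypeError(f"haplotypes span different ranges: {sorted(ranges)}")
    by_sites: dict[frozenset[int], list[Haplotype]] = {}
    for h in haplotypes:
        by_sites.setdefault(h.substitution_sites(), []).append(h)
    nodes = []
    for i, sites in enumerate(sorted(by_sites, key=lambda s: (len(s), sorted(s)))):
        members = by_sites[sites]
        nodes.append(
            NetworkNode(
                node_id=f"H{i + 1}",
                sites=sites,
                samples=tuple(
                    (h.sample_id, h.population, h.region_role) for h in members
                ),
            )
        )
    return nodes


def _distance(
    a: frozenset[int], b: frozenset[int], weights: Mapping[int, float]
) -> float:
    return sum(weights.get(p, 1.0) for p in a ^ b)


def _msn_edges(
    site_sets: Sequence[frozenset[int]],
    weights: Mapping[int, float],
    epsilon: float,
) -> list[tuple[int, int, float]]:
    """Feasible links of the epsilon-relaxed minimum spanning network.

    An edge (u, v) belongs to some minimum spanning tree iff its weight
    equals the minimax path weight between u and v (the heaviest edge on
    the u-v path of any MST).  The epsilon-relaxed network admits every
    edge within epsilon of that threshold; with epsilon=0 it is exactly the
    union of all MSTs.  Edge order is lexicographic by (weight, node ids)
    for determinism.
    """
    n = len(site_sets)
    if n < 2:
        return []
    thresholds = _merge_thresholds(site_sets, weights)
    feasible = [
        (u, v, d)
        for u, v in itertools.combinations(range(n), 2)
        if (d := _distance(site_sets[u], site_sets[v], weights))
        <= thresholds[(u, v)] + epsilon + 1e-9
    ]
    feasible.sort(key=lambda e: (e[2], e[0], e[1]))
    return feasible


def _merge_thresholds(
    site_sets: Sequence[frozenset[int]], weights: Mapping[int, float]
) -> dict[tuple[int, int], float]:
    """For each pair, the edge-weight class at which the pair's components
    merge in a Kruskal sweep (the minimax path weight)."""
    n = len(site_sets)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=_distance(site_sets[i], site_sets[j], weights))
    mst = nx.minimum_spanning_tree(g)
    thresholds: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        path = nx.shortest_path(mst, i, j)
        w = max(
            mst[u][v]["weight"] for u, v in zip(path, path[1:])
        )
        thresholds[(i, j)] = w
        thresholds[(j, i)] = w
    return thresholds


def _mst_weight(site_sets: Sequence[frozenset[int]], weights: Mapping[int, float]) -> float:
    g = nx.Graph()
    g.add_nodes_from(range(len(site_sets)))
    for i, j in itertools.combinations(range(len(site_sets)), 2):
        g.add_edge(i, j, weight=_distance(site_sets[i], site_sets[j], weights))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))


def _median(a: frozenset[int], b: frozenset[int], c: frozenset[int]) -> frozenset[int]:
    """Majority-consensus vector of three binary site sets."""
    return frozenset(
        p for p in a | b | c if (p in a) + (p in b) + (p in c) >= 2
    )


def build_mj_network(
    haplotypes_or_nodes: Sequence[Haplotype] | Sequence[NetworkNode],
    epsilon: float = 0.0,
    weights: Mapping[int, float] | None = None,
) -> HaploNetwork:
    """Build a median-joining network.

    Accepts raw haplotypes (condensed internally) or pre-condensed nodes.
    ``epsilon`` relaxes the spanning-network link criterion; ``weights``
    maps positions to positive per-position weights (default 1).

    The result is connected, contains an epsilon-relaxed minimum spanning
    network of the observed nodes (every observed-MSN adjacency is realised
    by a network path of no greater weight), and inferred median nodes are
    pruned when they no longer shorten the network.
    """
    weights = dict(weights or {})
    if haplotypes_or_nodes and isinstance(haplotypes_or_nodes[0], Haplotype):
        nodes = condense(haplotypes_or_nodes)  # type: ignore[arg-type]
    else:
        nodes = list(haplotypes_or_nodes)  # type: ignore[arg-type]
    if len(nodes) < 1:
        raise ValueError("need at least one haplotype")

    observed_sites = [n.sites for n in nodes]
    site_sets: list[frozenset[int]] = list(observed_sites)

    def mst_w(sets: Sequence[frozenset[int]]) -> float:
        return _mst_weight(sets, weights)

    if len(site_sets) > 1:
        for _iteration in range(MAX_MJ_ITERATIONS):
            links = _msn_edges(site_sets, weights, epsilon)
            adjacency: dict[int, set[int]] = {i: set() for i in range(len(site_sets))}
            for u, v, _w in links:
                adjacency[u].add(v)
                adjacency[v].add(u)
            # candidate medians: on small node sets every triple is tried;
            # larger runs restrict to triples (u, v, w) where u-v is a link
            # and w is linked to u or v (Bandelt's connected triplets)
            candidates: set[frozenset[int]] = set()
            existing = set(site_sets)
            if len(site_sets) <= 30:
                triples = itertools.combinations(range(len(site_sets)), 3)
                for u, v, w in triples:
                    m = _median(site_sets[u], site_sets[v], site_sets[w])
                    if m not in existing:
                        candidates.add(m)
            else:
                for u, v, _w in links:
                    for w in adjacency[u] | adjacency[v]:
                        if w in (u, v):
                            continue
                        m = _median(site_sets[u], site_sets[v], site_sets[w])
                        if m not in existing:
                            candidates.add(m)
            if not candidates:
                break
            base = mst_w(site_sets)
            ordered = sorted(candidates, key=sorted)
            best: tuple[float, tuple[int, ...]] | None = None
            for m in ordered:
                w_new = mst_w(site_sets + [m])
                key = (w_new, tuple(sorted(m)))
                if w_new < base - 1e-9 and (best is None or key < best):
                    best = key
            # a greedy single addition can land in a local optimum that a
            # coordinated pair of medians avoids; the pair lookahead is
            # bounded so large runs stay cheap
            best_pair: tuple[float, tuple, tuple] | None = None
            if len(ordered) <= 60:
                for m1, m2 in itertools.combinations(ordered, 2):
                    w_new = mst_w(site_sets + [m1, m2])
                    key = (w_new, tuple(sorted(m1)), tuple(sorted(m2)))
                    if w_new < base - 1e-9 and (best_pair is None or key < best_pair):
                        best_pair = key
            if best_pair is not None and (best is None or best_pair[0] < best[0] - 1e-9):
                site_sets.append(frozenset(best_pair[1]))
                site_sets.append(frozenset(best_pair[2]))
            elif best is not None:
                site_sets.append(frozenset(best[1]))
            else:
                break
        else:
            raise ConvergenceError(
                f"median joining did not converge within {MAX_MJ_ITERATIONS} iterations"
            )

        # prune obsolete inferred nodes: remove any median whose deletion
        # does not increase the spanning cost (greedy, deterministic order)
        changed = True
        while changed:
            changed = False
            for idx in range(len(site_sets) - 1, len(observed_sites) - 1, -1):
                trial = site_sets[:idx] + site_sets[idx + 1 :]
                if mst_w(trial) <= mst_w(site_sets) + 1e-9:
                    site_sets = trial
                    changed = True

    # assemble final graph: MSN over the final (observed + median) node set,
    # plus the MSN over observed nodes alone — median chains can otherwise
    # displace an equally parsimonious direct alternative link, and the
    # network is meant to display all shortest alternative connections
    node_objs: dict[str, NetworkNode] = {}
    id_of: dict[int, str] = {}
    median_counter = 0
    for i, sites in enumerate(site_sets):
        if i < len(nodes):
            node = nodes[i]
        else:
            median_counter += 1
            node = NetworkNode(
                node_id=f"mv{median_counter}", sites=sites, inferred=True
            )
        node_objs[node.node_id] = node
        id_of[i] = node.node_id

    graph = nx.Graph()
    for nid, node in node_objs.items():
        graph.add_node(nid, inferred=node.inferred, multiplicity=node.multiplicity)
    final_edges = _msn_edges(site_sets, weights, epsilon)
    observed_edges = _msn_edges(observed_sites, weights, epsilon)
    for u, v, w in final_edges + observed_edges:
        graph.add_edge(
            id_of[u],
            id_of[v],
            weight=w,
            positions=frozenset(site_sets[u] ^ site_sets[v]),
        )
    if len(node_objs) > 1 and not nx.is_connected(graph):
        raise ConvergenceError("network is not connected")  # pragma: no cover
    return HaploNetwork(graph=graph, nodes=node_objs, epsilon=epsilon, weights=weights)


def write_edge_list(network: HaploNetwork, path) -> None:
    """TSV edge list: node_id, node_id, comma-joined positions, weight."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tpositions\tweight\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            pos = ",".join(map(str, sorted(d["positions"])))
            fh.write(f"{u}\t{v}\t{pos}\t{d['weight']:g}\n")


def write_graphml(network: HaploNetwork, path) -> None:
    """GraphML export (positions flattened to comma-joined strings)."""
    g = nx.Graph()
    for nid, node in network.nodes.items():
        g.add_node(
            nid,
            inferred=node.inferred,
            multiplicity=node.multiplicity,
            sites=",".join(map(str, sorted(node.sites))),
            populations=",".join(sorted(node.populations())),
        )
    for u, v, d in network.graph.edges(data=True):
        g.add_edge(
            u, v, weight=float(d["weight"]),
            positions=",".join(map(str, sorted(d["positions"]))),
        )
    nx.write_graphml(g, path)
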