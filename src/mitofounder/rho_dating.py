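"""Rho-statistic coalescence dating with molecular-clock calibrations.

The rho statistic is the mean number of mutations from a clade's root to
its sampled tips.  Multiplying rho by a clock (years per mutation) gives an
estimate of the clade's age (TMRCA).  The standard error follows the
branch-wise Poisson variance: treating each mutation count as a Poisson
observation, Var(rho) = sum over branches of (n_b / n)^2 * m_b, where n_b
is the number of sampled leaves below branch b and m_b the mutations on it.

Clock calibrations bundled here (years per mutation):

========== ======== ==============================================
label      value    scope
========== ======== ==============================================
wholemt     3,624   any substitution, complete mitogenome
synonymous  7,884   synonymous substitutions only
hvs1       16,677   HVS-I control-region mutations
fa_complete 2,643   complete-mitogenome founder analysis (central
                    value between young and old founder rates)
========== ======== ==============================================

These calibrations already account for purifying selection; no additional
rate correction is applied here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "ClockSpec",
    "CLOCKS",
    "ClusterTree",
    "rho",
    "rho_sigma",
    "rho_to_age",
    "site_class_filter",
    "tree_from_paths",
    "parse_newick_counts",
]


@dataclass(frozen=True)
class ClockSpec:
    """A molecular-clock calibration: years per mutation."""

    label: str
    years_per_mutation: float

    def __post_init__(self) -> None:
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")


CLOCKS: dict[str, ClockSpec] = {
    "wholemt": ClockSpec("wholemt", 3_624.0),
    "synonymous": ClockSpec("synonymous", 7_884.0),
    "hvs1": ClockSpec("hvs1", 16_677.0),
    "fa_complete": ClockSpec("fa_complete", 2_643.0),
}


def get_clock(clock: str | ClockSpec) -> ClockSpec:
    if isinstance(clock, ClockSpec):
        return clock
    try:
        return CLOCKS[clock]
    except KeyError:
        raise KeyError(
            f"unknown clock {clock!r}; available: {', '.join(sorted(CLOCKS))}"
        ) from None


@dataclass
class ClusterTree:
    """A rooted mutation-count tree for rho dating.

    Each node's parent branch carries ``mutations`` — either an integer
    count or an explicit tuple of mutated rCRS positions (needed for
    site-class filtering).  The root's branch is empty by construction.
    """

    label: str = ""
    mutations: tuple[int, ...] | int = 0
    children: list["ClusterTree"] = field(default_factory=list)

    @property
    def m(self) -> int:
        """Mutation count on the parent branch."""
        return self.mutations if isinstance(self.mutations, int) else len(self.mutations)

    def n_leaves(self) -> int:
        if not self.children:
            return 1
        return sum(c.n_leaves() for c in self.children)

    def leaves(self) -> list["ClusterTree"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def branches(self) -> list["ClusterTree"]:
        """All nodes except the root, i.e. all parent branches."""
        out = []
        for c in self.children:
            out.append(c)
            out.extend(c.branches())
        return out


def rho(tree: ClusterTree) -> float:
    """Mean root-to-leaf mutation count: rho = sum_b (n_b/n) m_b."""
    n = tree.n_leaves()
    if n < 1:
        raise ValueError("empty tree")
    return sum(b.n_leaves() / n * b.m for b in tree.branches())


def rho_sigma(tree: ClusterTree) -> float:
    """Standard error of rho under branch-wise Poisson mutation counts.

    sigma^2 = sum_b (n_b/n)^2 m_b.
    """
    n = tree.n_leaves()
    if n < 1:
        raise ValueError("empty tree")
    var = sum((b.n_leaves() / n) ** 2 * b.m for b in tree.branches())
    return var ** 0.5


def rho_to_age(
    rho_value: float, sigma: float, clock: str | ClockSpec
) -> tuple[float, tuple[float, float]]:
    """Convert rho (and its standard error) to an age in years.

    age = rho * years_per_mutation; the 95% CI is the normal approximation
    age +/- 1.96 * sigma * years_per_mutation, floored at 0.
    """
    if rho_value < 0 or sigma < 0:
        raise ValueError("rho and sigma must be non-negative")
    spec = get_clock(clock)
    age = rho_value * spec.years_per_mutation
    half = 1.96 * sigma * spec.years_per_mutation
    return age, (max(0.0, age - half), age + half)


def site_class_filter(
    tree: ClusterTree,
    site_class_table: Mapping[int, str],
    keep: Iterable[str] = ("synonymous",),
) -> ClusterTree:
    """Recount branch mutations keeping only positions of the given classes.

    Every branch must carry explicit mutated positions, and every position
    must be classified in ``site_class_table`` (values like 'synonymous',
    'nonsynonymous', 'rna', 'control'); unclassified positions raise with
    the offending list.
    """
    keep_set = set(keep)
    unclassified: set[int] = set()

    def walk(node: ClusterTree) -> ClusterTree:
        if isinstance(node.mutations, int):
            if node.mutations and node is not tree:
                raise ValueError(
                    f"branch {node.label!r} has a bare count; site-class "
                    "filtering needs explicit mutation positions"
                )
            kept: tuple[int, ...] | int = ()
        else:
            missing = [p for p in node.mutations if p not in site_class_table]
            if missing:
                unclassified.update(missing)
                kept = ()
            else:
                kept = tuple(
                    p for p in node.mutations if site_class_table[p] in keep_set
                )
        return ClusterTree(
            label=node.label, mutations=kept, children=[walk(c) for c in node.children]
        )

    out = walk(tree)
    if unclassified:
        raise ValueError(
            "unclassified position(s): " + ", ".join(map(str, sorted(unclassified)))
        )
    return out


def tree_from_paths(
    paths: Mapping[str, Sequence[int]], root_label: str = "founder"
) -> ClusterTree:
    """Build a ClusterTree from per-leaf root paths of branch mutation counts.

    ``paths`` maps each leaf label to the sequence of per-edge mutation
    counts along its path from the root; shared path prefixes (same counts
    at the same depth AND same intermediate node identity) are NOT merged —
    each leaf hangs off the root through its own chain.  This is the
    star-of-chains reduction used when leaves' network paths to a founder
    are known individually; rho and sigma only depend on per-leaf path
    sums and per-branch leaf counts, which this construction preserves for
    unshared paths.
    """
    root = ClusterTree(label=root_label)
    for leaf, counts in sorted(paths.items()):
        node = root
        for depth, c in enumerate(counts):
            child = ClusterTree(label=f"{leaf}@{depth}", mutations=int(c))
            node.children.append(child)
            node = child
        if not counts:
            node.children.append(ClusterTree(label=f"{leaf}@0", mutations=0))
    return root


_NEWICK_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+|:")


def parse_newick_counts(text: str) -> ClusterTree:
    """Parse a Newick string whose branch lengths are integer mutation counts.

    Example: ``((a:1,b:0):2,c:3);`` — lengths must be non-negative integers
    (they are mutation counts, not time).
    """
    pos = 0
    text = text.strip()

    def parse_node() -> ClusterTree:
        nonlocal pos
        node = ClusterTree()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character at {pos}: {text[pos]!r}")
        m = re.match(r"[^(),:;]*", text[pos:])
        node.label = m.group(0).strip()
        pos += m.end()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"\d+", text[pos:])
            if m is None:
                raise ValueError(
                    f"branch length at {pos} is not a non-negative integer"
                )
            node.mutations = int(m.group(0))
            pos += m.end()
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise ValueError("newick string must end with ';'")
    return root
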