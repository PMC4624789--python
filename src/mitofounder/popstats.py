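"""Population summary statistics for mtDNA haplotype data.

Frequency tables with African-lineage totals, the mean number of pairwise
differences (MNPD), and a pairwise-difference population differentiation
statistic (PhiST-like F_ST analogue) with a permutation significance test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .haplotype_io import HaploFreqTable, Haplotype, HaplotypeError

__all__ = [
    "DiversitySummary",
    "frequency_table",
    "mnpd",
    "pairwise_differences",
    "fst_permutation",
    "diversity_summary",
]

#: Rows of a count table that belong to the African maternal pool: U6 and M1
#: (North/East African) plus every L (sub-Saharan) lineage.
AFRICAN_MAJORS = ("U6", "M1", "L")


def _round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how published tables are rendered
    (Python's built-in round is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def frequency_table(
    counts: HaploFreqTable,
    *,
    african_majors: Sequence[str] = AFRICAN_MAJORS,
    ndigits: int = 2,
) -> pd.DataFrame:
    """Percentage table from haplogroup counts, plus an African-lineage total.

    Percentages are 100*count/n rounded half-up to ``ndigits`` decimals.  The
    derived row ``African lineages`` sums the major-haplogroup rows (by
    default U6 + M1 + L); sub-haplogroup rows (e.g. ``U6a`` under ``U6``) are
    not double counted because only the named major rows enter the total.

    Returns a DataFrame indexed by haplogroup with a two-level column index
    (population, {'n', '%'}).
    """
    pops = [p for p, _ in counts.populations]
    ns = {p: n for p, n in counts.populations}
    data: dict[tuple[str, str], list[float]] = {}
    labels = [label for label, _ in counts.rows]
    major_totals = np.zeros(len(pops), dtype=int)
    row_map = dict(counts.rows)
    for major in african_majors:
        if major not in row_map:
            raise HaplotypeError(f"count table lacks required major row {major!r}")
        major_totals += np.asarray(row_map[major], dtype=int)
    for j, pop in enumerate(pops):
        n = ns[pop]
        col_counts = [row_map[label][j] for label in labels]
        col_counts.append(int(major_totals[j]))
        data[(pop, "n")] = col_counts
        data[(pop, "%")] = [
            _round_half_up(100.0 * c / n, ndigits) for c in col_counts
        ]
    index = labels + ["African lineages"]
    return pd.DataFrame(data, index=pd.Index(index, name="haplogroup"))


def pairwise_differences(a: Haplotype, b: Haplotype) -> int:
    """Number of positions at which two haplotypes carry different states.

    Counted over the union of called positions, so a call present in one
    haplotype and absent in the other (i.e. rCRS state) is one difference,
    and two different derived alleles at the same position also count once.
    """
    calls_a = {(v.position, v.insertion_index): v for v in a.variants}
    calls_b = {(v.position, v.insertion_index): v for v in b.variants}
    diff = 0
    for key in set(calls_a) | set(calls_b):
        va, vb = calls_a.get(key), calls_b.get(key)
        if va is None or vb is None:
            diff += 1
        elif (va.derived_allele, va.kind) != (vb.derived_allele, vb.kind):
            diff += 1
    return diff


def mnpd(haplotypes: Sequence[Haplotype]) -> float:
    """Mean number of pairwise differences over all unordered pairs."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError("MNPD requires at least 2 haplotypes")
    ranges = {h.range for h in haplotypes}
    if len(ranges) > 1:
        raise HaplotypeError(f"haplotypes span different ranges: {sorted(ranges)}")
    total = sum(
        pairwise_differences(a, b) for a, b in itertools.combinations(haplotypes, 2)
    )
    return total / (n * (n - 1) / 2)


def _fst_from_matrix(d: np.ndarray, labels: np.ndarray) -> float:
    """PhiST-like statistic from a pairwise difference matrix and 0/1 labels.

    (mean between-group difference - mean within-group difference) / mean
    between.  Within-group pairs from both groups are pooled.  Degenerate
    inputs (no between-group variation) return 0 by convention.
    """
    in_a = labels == 0
    in_b = ~in_a
    between = d[np.ix_(in_a, in_b)]
    mean_between = between.mean() if between.size else 0.0
    within_vals: list[float] = []
    for mask in (in_a, in_b):
        sub = d[np.ix_(mask, mask)]
        iu = np.triu_indices_from(sub, k=1)
        within_vals.extend(sub[iu])
    mean_within = float(np.mean(within_vals)) if within_vals else 0.0
    if mean_between == 0.0:
        return 0.0
    return float((mean_between - mean_within) / mean_between)


def fst_permutation(
    group_a: Sequence[Haplotype],
    group_b: Sequence[Haplotype],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pairwise-difference F_ST between two groups with permutation p-value.

    The statistic is the PhiST-like quantity of :func:`_fst_from_matrix`;
    negative values are reported as-is.  The p-value is the fraction of
    permuted label assignments with F_ST >= the observed value (the observed
    labelling is included among the permutations, so p > 0 always).  When the
    number of distinct label splits C(n, n_a) does not exceed ``n_perm``,
    all splits are enumerated and the p-value is exact and seed-independent;
    otherwise ``n_perm`` random permutations are drawn from ``seed``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    hs = list(group_a) + list(group_b)
    n_a = len(group_a)
    n = len(hs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_differences(hs[i], hs[j])
    labels = np.array([0] * n_a + [1] * (n - n_a))
    observed = _fst_from_matrix(d, labels)
    if d.max() == 0:  # all haplotypes identical
        return 0.0, 1.0

    n_splits = math.comb(n, n_a)
    eps = 1e-12
    if n_splits <= n_perm:
        hits = 0
        for combo in itertools.combinations(range(n), n_a):
            perm = np.ones(n, dtype=int)
            perm[list(combo)] = 0
            if _fst_from_matrix(d, perm) >= observed - eps:
                hits += 1
        return observed, hits / n_splits
    rng = np.random.default_rng(seed)
    hits = 1  # the observed labelling itself
    for _ in range(n_perm - 1):
        perm = rng.permutation(labels)
        if _fst_from_matrix(d, perm) >= observed - eps:
            hits += 1
    return observed, hits / n_perm


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    n: int
    mnpd: float
    haplogroup_percent: dict[str, float]


def diversity_summary(
    haplotypes: Sequence[Haplotype], population: str | None = None
) -> DiversitySummary:
    """MNPD and haplogroup percentages for one population sample."""
    hs = (
        [h for h in haplotypes if h.population == population]
        if population is not None
        else list(haplotypes)
    )
    if not hs:
        raise ValueError(f"no haplotypes for population {population!r}")
    n = len(hs)
    groups: dict[str, int] = {}
    for h in hs:
        if h.haplogroup:
            groups[h.haplogroup] = groups.get(h.haplogroup, 0) + 1
    return DiversitySummary(
        population=population or hs[0].population,
        n=n,
        mnpd=mnpd(hs) if n >= 2 else 0.0,
        haplogroup_percent={
            g: _round_half_up(100.0 * c / n) for g, c in sorted(groups.items())
        },
    )
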