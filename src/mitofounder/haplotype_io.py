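"""Parsing, validation and filtering of mtDNA haplotypes.

Haplotypes are scored as sets of variant calls against the rCRS coordinate
system (1-based positions 1..16569).  Control-region data are restricted by
default to the HVS-I range 16051-16400.  The variant-string dialect is the
EMPOP convention used for forensic and population control-region data:

* ``16172C``    substitution to C at position 16172
* ``16183.1C``  insertion of C after position 16183 (sub-index 1)
* ``16189d``    deletion at 16189 (``16189del`` also accepted)
* ``16093Y``    IUPAC ambiguity code, treated as a heteroplasmic call

The module also handles the standard pre-phylogenetic cleanup for HVS-I:
dropping the hypermutable 16182C/16183C calls and position 16519, and
discarding indels and heteroplasmies, which carry little phylogenetic
signal at this scale.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantKind",
    "VariantCall",
    "Haplotype",
    "HaploFreqTable",
    "FilterPolicy",
    "HaplotypeError",
    "VariantParseError",
    "RangeError",
    "CoverageError",
    "MotifTableError",
    "HVS1_RANGE",
    "FULL_RANGE",
    "MT_LENGTH",
    "DEFAULT_ASSAY_TABLE",
    "BUNDLED_MOTIF_TABLE",
    "parse_variant_string",
    "format_variant_string",
    "filter_positions",
    "classify_diagnostic_snp",
    "assign_haplogroup_motif",
    "haplotype_from_sequence",
    "synthetic_reference",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_freq_table",
]

MT_LENGTH = 16569
HVS1_RANGE = (16051, 16400)
FULL_RANGE = (1, MT_LENGTH)

IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
BASES = set("ACGT")


class HaplotypeError(ValueError):
    """Base class for haplotype input errors."""


class VariantParseError(HaplotypeError):
    """A variant token does not match the grammar."""


class RangeError(HaplotypeError):
    """A position falls outside the declared haplotype range."""


class CoverageError(HaplotypeError):
    """An assayed position is not covered by the haplotype's range."""


class MotifTableError(HaplotypeError):
    """The haplogroup motif hierarchy is malformed (e.g. cyclic)."""


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    HETEROPLASMY = "heteroplasmy"


@dataclass(frozen=True, order=True)
class VariantCall:
    """One scored difference from rCRS.

    ``insertion_index`` is the sub-index of an inserted base (the ``.1`` in
    ``16183.1C``); it is 0 for every other kind.
    """

    position: int
    derived_allele: str
    kind: VariantKind
    insertion_index: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.position <= MT_LENGTH):
            raise RangeError(
                f"position {self.position} outside rCRS coordinates 1..{MT_LENGTH}"
            )
        if self.kind is VariantKind.INSERTION and self.insertion_index < 1:
            raise VariantParseError(
                f"insertion at {self.position} lacks a sub-index token"
            )

    def token(self) -> str:
        """Render back to the EMPOP-style token."""
        if self.kind is VariantKind.DELETION:
            return f"{self.position}d"
        if self.kind is VariantKind.INSERTION:
            return f"{self.position}.{self.insertion_index}{self.derived_allele}"
        return f"{self.position}{self.derived_allele}"


@dataclass(frozen=True)
class Haplotype:
    """A sample's mtDNA haplotype: variant calls over a declared range.

    The variant set defines the haplotype relative to rCRS; an empty set
    means identity with the reference over ``range``.
    """

    sample_id: str = ""
    population: str = ""
    region_role: str = "unassigned"  # source | sink | unassigned
    range: tuple[int, int] = HVS1_RANGE
    variants: frozenset[VariantCall] = frozenset()
    haplogroup: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.range
        if lo > hi:
            raise RangeError(f"empty range {lo}..{hi}")
        bad = sorted(v.token() for v in self.variants if not lo <= v.position <= hi)
        if bad:
            raise RangeError(
                f"variant(s) outside range {lo}..{hi}: {', '.join(bad)}"
            )
        seen: dict[tuple[int, int], VariantCall] = {}
        for v in self.variants:
            key = (v.position, v.insertion_index)
            if key in seen and v.kind is seen[key].kind is VariantKind.SUBSTITUTION:
                raise HaplotypeError(
                    f"duplicate substitution calls at position {v.position}"
                )
            seen[key] = v

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.variants)

    def substitution_sites(self) -> frozenset[int]:
        """Positions carrying a substitution call (the binary network state)."""
        return frozenset(
            v.position for v in self.variants if v.kind is VariantKind.SUBSTITUTION
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_variant_string(self)


_TOKEN_RE = re.compile(
    r"""^(?P<pos>\d+)
        (?:
            \.(?P<ins_idx>\d+)(?P<ins_base>[ACGT])   # insertion 16183.1C
          | (?P<del>d(?:el)?)                        # deletion 16189d / 16189del
          | (?P<allele>[A-Za-z])                     # substitution / ambiguity
        )$""",
    re.VERBOSE,
)


def parse_variant_string(
    text: str,
    range: tuple[int, int] = HVS1_RANGE,
    *,
    sample_id: str = "",
    population: str = "",
    region_role: str = "unassigned",
    haplogroup: str | None = None,
    reference: str | None = None,
) -> Haplotype:
    """Parse a whitespace-separated EMPOP-style variant string.

    Parameters
    ----------
    text
        e.g. ``"16172C 16219G"``; the empty string denotes identity to rCRS.
    range
        Closed 1-based interval of rCRS coordinates the calls must lie in.
    reference
        Optional full-length reference sequence; when given, substitutions
        identical to the reference base are rejected.

    Raises
    ------
    VariantParseError
        naming every malformed token.
    RangeError
        naming every token outside ``range``.
    """
    calls: list[VariantCall] = []
    bad_tokens: list[str] = []
    out_of_range: list[str] = []
    for token in text.split():
        m = _TOKEN_RE.match(token)
        if m is None:
            bad_tokens.append(token)
            continue
        pos = int(m.group("pos"))
        if not range[0] <= pos <= range[1]:
            out_of_range.append(token)
            continue
        if m.group("del"):
            calls.append(VariantCall(pos, "-", VariantKind.DELETION))
        elif m.group("ins_base"):
            calls.append(
                VariantCall(
                    pos,
                    m.group("ins_base"),
                    VariantKind.INSERTION,
                    int(m.group("ins_idx")),
                )
            )
        else:
            allele = m.group("allele").upper()
            if allele in BASES:
                if reference is not None and reference[pos - 1].upper() == allele:
                    bad_tokens.append(token + " (identical to reference)")
                    continue
                calls.append(VariantCall(pos, allele, VariantKind.SUBSTITUTION))
            elif allele in IUPAC_AMBIGUITY:
                calls.append(VariantCall(pos, allele, VariantKind.HETEROPLASMY))
            else:
                bad_tokens.append(token)
    if bad_tokens:
        raise VariantParseError(f"malformed variant token(s): {', '.join(bad_tokens)}")
    if out_of_range:
        raise RangeError(
            f"position(s) outside range {range[0]}..{range[1]}: "
            + ", ".join(out_of_range)
        )
    return Haplotype(
        sample_id=sample_id,
        population=population,
        region_role=region_role,
        range=range,
        variants=frozenset(calls),
        haplogroup=haplogroup,
    )


def format_variant_string(h: Haplotype) -> str:
    """Serialize a haplotype back to its variant string (sorted by position)."""
    ordered = sorted(h.variants, key=lambda v: (v.position, v.insertion_index))
    return " ".join(v.token() for v in ordered)


@dataclass(frozen=True)
class FilterPolicy:
    """Which calls to drop before phylogenetic analysis.

    ``excluded`` maps positions to either a set of alleles to drop at that
    position or ``None`` meaning drop any call there.  The default mirrors
    standard HVS-I practice: 16182C and 16183C (poly-C tract artefacts,
    C calls only) and 16519 for any allele; indels and heteroplasmies are
    dropped as well.
    """

    excluded: Mapping[int, frozenset[str] | None] = field(
        default_factory=lambda: {
            16182: frozenset({"C"}),
            16183: frozenset({"C"}),
            16519: None,
        }
    )
    drop_indels: bool = True
    drop_heteroplasmy: bool = True

    def keeps(self, v: VariantCall) -> bool:
        if self.drop_indels and v.kind in (VariantKind.INSERTION, VariantKind.DELETION):
            return False
        if self.drop_heteroplasmy and v.kind is VariantKind.HETEROPLASMY:
            return False
        if v.position in self.excluded:
            alleles = self.excluded[v.position]
            if alleles is None or v.derived_allele in alleles:
                return False
        return True


DEFAULT_FILTER_POLICY = FilterPolicy()


def filter_positions(h: Haplotype, policy: FilterPolicy = DEFAULT_FILTER_POLICY) -> Haplotype:
    """Return a new haplotype with excluded calls removed (idempotent)."""
    kept = frozenset(v for v in h.variants if policy.keeps(v))
    return replace(h, variants=kept)


# --- diagnostic SNP screening -------------------------------------------------

#: TaqMan-style diagnostic assays: position -> {derived allele -> label}.
#: 3348G marks haplogroup U6; 10873C marks the L/M macro-lineages.
DEFAULT_ASSAY_TABLE: dict[int, dict[str, str]] = {
    3348: {"G": "U6"},
    10873: {"C": "L/M"},
}


def classify_diagnostic_snp(
    h: Haplotype, assay_table: Mapping[int, Mapping[str, str]] = DEFAULT_ASSAY_TABLE
) -> str | list[str]:
    """Screen a (full-genome range) haplotype against diagnostic SNP assays.

    Returns the matching label, ``"none"`` if no assay allele is present, or
    a list of labels when several assays match.
    """
    lo, hi = h.range
    uncovered = [p for p in assay_table if not lo <= p <= hi]
    if uncovered:
        raise CoverageError(
            f"assayed position(s) outside haplotype range {lo}..{hi}: "
            + ", ".join(map(str, sorted(uncovered)))
        )
    alleles = {
        (v.position, v.derived_allele)
        for v in h.variants
        if v.kind is VariantKind.SUBSTITUTION
    }
    labels = [
        label
        for pos, mapping in sorted(assay_table.items())
        for allele, label in sorted(mapping.items())
        if (pos, allele) in alleles
    ]
    if not labels:
        return "none"
    if len(labels) == 1:
        return labels[0]
    return labels


# --- haplogroup motif assignment ----------------------------------------------

#: Minimal illustrative motif hierarchy (label -> (parent, required variants)).
#: Motifs are HVS-I substitution positions with derived alleles; this table
#: covers the major African lineages discussed in the package and is meant
#: to be replaced by a user-supplied table for serious classification work.
BUNDLED_MOTIF_TABLE: dict[str, tuple[str | None, frozenset[str]]] = {
    "mt-root": (None, frozenset()),
    "U6": ("mt-root", frozenset({"16172C", "16219G"})),
    "U6a": ("U6", frozenset({"16172C", "16219G", "16278T"})),
    "M1": ("mt-root", frozenset({"16129A", "16189C", "16249C", "16311C"})),
    "L1b": ("mt-root", frozenset({"16126C", "16187T", "16189C", "16223T", "16264T", "16270T", "16278T", "16311C"})),
    "L2": ("mt-root", frozenset({"16223T", "16278T", "16390A"})),
    "L3": ("mt-root", frozenset({"16223T"})),
}


def _motif_depths(
    motif_table: Mapping[str, tuple[str | None, frozenset[str]]]
) -> dict[str, int]:
    depths: dict[str, int] = {}

    def depth(label: str, trail: tuple[str, ...] = ()) -> int:
        if label in trail:
            raise MotifTableError(
                "cyclic motif hierarchy: " + " -> ".join(trail + (label,))
            )
        if label in depths:
            return depths[label]
        parent = motif_table[label][0]
        d = 0 if parent is None else depth(parent, trail + (label,)) + 1
        depths[label] = d
        return d

    for label in motif_table:
        depth(label)
    return depths


def assign_haplogroup_motif(
    h: Haplotype,
    motif_table: Mapping[str, tuple[str | None, frozenset[str]]] = BUNDLED_MOTIF_TABLE,
) -> str | list[str]:
    """Assign the deepest haplogroup whose full motif the haplotype carries.

    The motif table is a hierarchy ``label -> (parent_label, motif tokens)``;
    a root label has parent ``None`` and an empty motif.  Returns the single
    deepest matching label, or a sorted list when two labels at the maximal
    depth tie (a flagged collision the caller must resolve).
    """
    depths = _motif_depths(motif_table)
    tokens = {v.token() for v in h.variants}
    matches = [
        label
        for label, (_, motif) in motif_table.items()
        if motif and motif <= tokens
    ]
    if not matches:
        roots = [lab for lab, (parent, _) in motif_table.items() if parent is None]
        if not roots:
            raise MotifTableError("motif table has no root label")
        return roots[0]
    best = max(depths[m] for m in matches)
    deepest = sorted(m for m in matches if depths[m] == best)
    return deepest[0] if len(deepest) == 1 else deepest


# --- sequence input -----------------------------------------------------------

def synthetic_reference(length: int = MT_LENGTH, seed: int = 20151005) -> str:
    """A synthetic stand-in reference sequence.

    This is NOT the rCRS: it is a deterministic pseudo-random base string of
    the right length, provided so that the FASTA comparison path and the
    simulator can run self-contained.  For real data, pass the genuine rCRS
    sequence (e.g. loaded from a user-supplied FASTA of NC_012920.1).
    """
    import random

    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(length))


def haplotype_from_sequence(
    seq: str,
    reference: str,
    range: tuple[int, int] = HVS1_RANGE,
    **annotations: str,
) -> Haplotype:
    """Score an aligned (gap-free) sequence slice against a reference slice.

    ``seq`` must cover exactly ``range`` (length ``hi - lo + 1``); it is
    compared base-by-base to the reference slice.  IUPAC ambiguity codes
    become heteroplasmy calls; alignment with indels is out of scope since
    indels are excluded downstream anyway.
    """
    lo, hi = range
    expected = hi - lo + 1
    if len(seq) != expected:
        raise RangeError(
            f"sequence length {len(seq)} does not match range {lo}..{hi} "
            f"({expected} bp); align and slice first"
        )
    if len(reference) < hi:
        raise RangeError(f"reference shorter than range end {hi}")
    calls = []
    for offset, base in enumerate(seq.upper()):
        ref_base = reference[lo - 1 + offset].upper()
        if base == ref_base:
            continue
        pos = lo + offset
        if base in BASES:
            calls.append(VariantCall(pos, base, VariantKind.SUBSTITUTION))
        elif base in IUPAC_AMBIGUITY:
            calls.append(VariantCall(pos, base, VariantKind.HETEROPLASMY))
        elif base == "-":
            calls.append(VariantCall(pos, "-", VariantKind.DELETION))
        else:
            raise VariantParseError(f"unexpected base {base!r} at {pos}")
    return Haplotype(range=range, variants=frozenset(calls), **annotations)


# --- tabular I/O --------------------------------------------------------------

def read_haplotype_table(
    path: str | Path,
    range: tuple[int, int] = HVS1_RANGE,
) -> list[Haplotype]:
    """Read a tab-separated haplotype table.

    Columns: ``sample_id  population  role  variants`` (header required;
    ``variants`` may be empty for rCRS-identical haplotypes; an optional
    ``haplogroup`` column is honoured).
    """
    haplotypes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "population", "role", "variants"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise HaplotypeError(
                f"haplotype table missing column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            haplotypes.append(
                parse_variant_string(
                    row["variants"] or "",
                    range=range,
                    sample_id=row["sample_id"],
                    population=row["population"],
                    region_role=row["role"] or "unassigned",
                    haplogroup=row.get("haplogroup") or None,
                )
            )
    return haplotypes


def write_haplotype_table(haplotypes: Iterable[Haplotype], path: str | Path) -> None:
    """Write haplotypes to the tab-separated dialect read_haplotype_table reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "population", "role", "variants", "haplogroup"])
        for h in haplotypes:
            writer.writerow(
                [
                    h.sample_id,
                    h.population,
                    h.region_role,
                    format_variant_string(h),
                    h.haplogroup or "",
                ]
            )


@dataclass(frozen=True)
class HaploFreqTable:
    """Haplogroup counts per population (rows x populations).

    ``populations`` pairs each label with its sample size n; ``rows`` maps a
    haplogroup label to its per-population counts (same order as
    ``populations``).
    """

    populations: tuple[tuple[str, int], ...]
    rows: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        width = len(self.populations)
        for label, counts in self.rows:
            if len(counts) != width:
                raise HaplotypeError(
                    f"row {label!r} has {len(counts)} counts for {width} populations"
                )
            if any(c < 0 for c in counts):
                raise HaplotypeError(f"negative count in row {label!r}")
        for j, (pop, n) in enumerate(self.populations):
            # top-level rows may nest sub-haplogroup rows, so only each
            # individual count is bounded by n, not the column total
            for label, counts in self.rows:
                if counts[j] > n:
                    raise HaplotypeError(
                        f"count {counts[j]} for {label!r} exceeds n={n} in {pop!r}"
                    )

    def count(self, label: str, population: str) -> int:
        j = [p for p, _ in self.populations].index(population)
        return dict(self.rows)[label][j]


def read_freq_table(path: str | Path) -> HaploFreqTable:
    """Read a haplogroup count table.

    Layout: first line ``haplogroup<TAB>pop1<TAB>pop2...``, second line
    ``n<TAB>n1<TAB>n2...`` with sample sizes, then one line per haplogroup
    with integer counts (``-`` or blank meaning zero).
    """
    with open(path, newline="") as fh:
        reader = list(csv.reader(fh, delimiter="\t"))
    if len(reader) < 2 or reader[1][0] != "n":
        raise HaplotypeError("count table needs a header line and an 'n' line")
    pops = reader[0][1:]
    ns = [int(x) for x in reader[1][1:]]
    rows = []
    for line in reader[2:]:
        if not line or not line[0].strip():
            continue
        counts = tuple(
            0 if x.strip() in ("", "-") else int(x) for x in line[1 : len(pops) + 1]
        )
        rows.append((line[0].strip(), counts))
    return HaploFreqTable(tuple(zip(pops, ns)), tuple(rows))
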