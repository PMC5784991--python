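"""Sequence-level genotyping of *Eisenia* worms from aligned COI and 28S.

The nuclear 28S marker distinguishes *E. andrei* (allele ``A``) from
*E. fetida* (allele ``F``) at a small set of species-diagnostic alignment
columns; Sanger consensus sequences of hybrids show two-base IUPAC
ambiguity codes at those columns.  The mitochondrial COI marker is
maternally inherited and assigns each worm to a haplogroup (``a``, ``f``
or ``f2``) by proximity in uncorrected p-distance.  Composing the two
calls yields the worm's genotype code (e.g. ``aAF``).

All alignment coordinates are 1-based.  Input residues are normalised to
uppercase; gaps (``-``) and ``N`` are treated as missing and removed
pairwise, never globally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .genotypes import GenotypeCode

UNAMBIGUOUS = frozenset("ACGT")

#: residue set denoted by each IUPAC nucleotide code (e.g. R -> {A, G})
IUPAC_SETS: Mapping[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
#: two-base ambiguity code for each unordered base pair (e.g. {A,G} -> R)
PAIR_TO_IUPAC: Mapping[frozenset[str], str] = {
    bases: code for code, bases in IUPAC_SETS.items() if len(bases) == 2
}


class AlignmentError(ValueError):
    """Sequences that should share a coordinate system do not."""


class UndefinedDistanceError(ValueError):
    """No comparable columns between two sequences."""


class CompositionError(ValueError):
    """A genotype code cannot be composed from ambiguous marker calls."""


@dataclass(frozen=True)
class AlignedSeq:
    """One aligned sequence of a given locus (``COI`` or ``28S``)."""

    id: str
    residues: str
    locus: str = "28S"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, column: int) -> str:
        """Residue at a 1-based alignment column."""
        return self.residues[column - 1]


@dataclass(frozen=True)
class DiagnosticSite:
    """Alignment column fixed for different bases in the two species."""

    column: int
    allele_A: str
    allele_F: str

    def __post_init__(self) -> None:
        if self.allele_A == self.allele_F:
            raise ValueError("diagnostic site alleles must differ")


@dataclass
class MarkerPanel:
    """Reference alignments plus their polymorphic and diagnostic sites."""

    locus: str
    refs_A: list[AlignedSeq]
    refs_F: list[AlignedSeq]
    polymorphic_sites: list[int] = field(default_factory=list)
    diagnostic_sites: list[DiagnosticSite] = field(default_factory=list)

    @classmethod
    def build(
        cls, refs_A: Sequence[AlignedSeq], refs_F: Sequence[AlignedSeq], locus: str = "28S"
    ) -> "MarkerPanel":
        """Discover polymorphic and diagnostic sites from reference sets."""
        panel = cls(locus=locus, refs_A=list(refs_A), refs_F=list(refs_F))
        panel.polymorphic_sites = find_polymorphic_sites(refs_A, refs_F)
        panel.diagnostic_sites = find_diagnostic_sites(refs_A, refs_F)
        return panel

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "polymorphic_sites": list(self.polymorphic_sites),
            "diagnostic_sites": [
                {"column": s.column, "allele_A": s.allele_A, "allele_F": s.allele_F}
                for s in self.diagnostic_sites
            ],
        }


@dataclass
class NuclearCall:
    """Diploid 28S call: AA, FF, AF (hybrid) or ambiguous."""

    genotype: str
    per_site: dict[int, str]
    n_het: int
    n_resolved: int


@dataclass
class MitoCall:
    """Maternal COI haplogroup assignment by mean p-distance."""

    clade: str
    mean_dist_to_best: float
    margin: float


def _check_alignment(seqs: Sequence[AlignedSeq]) -> int:
    if not seqs:
        raise ValueError("empty sequence set")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"aligned lengths differ: {sorted(lengths)}")
    loci = {s.locus for s in seqs}
    if len(loci) > 1:
        raise AlignmentError(f"mixed loci in one alignment: {sorted(loci)}")
    return lengths.pop()


def find_polymorphic_sites(
    refs_A: Sequence[AlignedSeq], refs_F: Sequence[AlignedSeq]
) -> list[int]:
    """1-based columns where the pooled references carry >=2 distinct bases.

    Gaps, ``N`` and ambiguity codes are ignored when counting distinct
    bases at a column.
    """
    pooled = list(refs_A) + list(refs_F)
    length = _check_alignment(pooled)
    out = []
    for col in range(1, length + 1):
        bases = {s.base(col) for s in pooled} & UNAMBIGUOUS
        if len(bases) >= 2:
            out.append(col)
    return out


def find_diagnostic_sites(
    refs_A: Sequence[AlignedSeq], refs_F: Sequence[AlignedSeq]
) -> list[DiagnosticSite]:
    """Polymorphic columns fixed for one base in A references and a
    different base in F references (species-diagnostic sites)."""
    if not refs_A or not refs_F:
        raise ValueError("both reference sets must be non-empty")
    _check_alignment(list(refs_A) + list(refs_F))
    sites = []
    for col in find_polymorphic_sites(refs_A, refs_F):
        bases_A = {s.base(col) for s in refs_A}
        bases_F = {s.base(col) for s in refs_F}
        if (
            len(bases_A) == 1
            and len(bases_F) == 1
            and bases_A <= UNAMBIGUOUS
            and bases_F <= UNAMBIGUOUS
            and bases_A != bases_F
        ):
            sites.append(
                DiagnosticSite(column=col, allele_A=bases_A.pop(), allele_F=bases_F.pop())
            )
    return sites


def call_nuclear(
    query: AlignedSeq,
    panel: MarkerPanel,
    het_fraction: float = 0.8,
    min_het_sites: int = 2,
) -> NuclearCall:
    """Score a 28S query at the panel's diagnostic sites.

    Each diagnostic column is scored ``homA`` (base equals the A allele),
    ``homF``, ``het`` (the two-base IUPAC code covering exactly both
    alleles) or ``unresolved``.  The genotype is ``AA``/``FF`` when all
    resolved sites are the matching homozygote, ``AF`` when at least
    ``het_fraction`` of resolved sites (and at least ``min_het_sites``)
    are heterozygous, and ``ambiguous`` otherwise — in particular for
    mixed homA/homF patterns without ambiguity codes, a possible
    contamination signal.
    """
    per_site: dict[int, str] = {}
    for site in panel.diagnostic_sites:
        base = query.base(site.column)
        het_code = PAIR_TO_IUPAC.get(frozenset({site.allele_A, site.allele_F}))
        if base == site.allele_A:
            per_site[site.column] = "homA"
        elif base == site.allele_F:
            per_site[site.column] = "homF"
        elif base == het_code:
            per_site[site.column] = "het"
        else:
            per_site[site.column] = "unresolved"
    statuses = [s for s in per_site.values() if s != "unresolved"]
    n_resolved = len(statuses)
    n_het = statuses.count("het")
    if n_resolved == 0:
        warnings.warn(
            f"no resolved diagnostic sites for {query.id}; nuclear call ambiguous",
            stacklevel=2,
        )
        genotype = "ambiguous"
    elif all(s == "homA" for s in statuses):
        genotype = "AA"
    elif all(s == "homF" for s in statuses):
        genotype = "FF"
    elif n_het / n_resolved >= het_fraction and n_het >= min_het_sites:
        genotype = "AF"
    else:
        genotype = "ambiguous"
    return NuclearCall(genotype=genotype, per_site=per_site, n_het=n_het, n_resolved=n_resolved)


def p_distance(s1: AlignedSeq, s2: AlignedSeq) -> float:
    """Uncorrected pairwise distance: mismatches over comparable columns.

    Columns where either sequence carries a gap, ``N`` or an ambiguity
    code are excluded pairwise.
    """
    if len(s1) != len(s2):
        raise AlignmentError(f"length mismatch: {len(s1)} vs {len(s2)}")
    if s1.locus != s2.locus:
        raise AlignmentError(f"locus mismatch: {s1.locus} vs {s2.locus}")
    comparable = 0
    mismatches = 0
    for b1, b2 in zip(s1.residues, s2.residues):
        if b1 in UNAMBIGUOUS and b2 in UNAMBIGUOUS:
            comparable += 1
            if b1 != b2:
                mismatches += 1
    if comparable == 0:
        raise UndefinedDistanceError(
            f"no comparable columns between {s1.id} and {s2.id}"
        )
    return mismatches / comparable


def group_p_distance(
    group_x: Sequence[AlignedSeq], group_y: Sequence[AlignedSeq]
) -> float:
    """Arithmetic mean of all between-group pairwise p-distances."""
    if not group_x or not group_y:
        raise ValueError("both groups must be non-empty")
    dists = [p_distance(x, y) for x in group_x for y in group_y]
    return sum(dists) / len(dists)


def cluster_sequences(
    seqs: Sequence[AlignedSeq], link_threshold: float = 0.05
) -> list[list[str]]:
    """Single-linkage partition of sequences on p-distance.

    Two sequences share a cluster iff they are connected by a chain of
    pairwise distances strictly below ``link_threshold``.  Clusters are
    returned sorted by size (largest first), ties and members ordered by
    lexicographic sequence id, so the partition is deterministic.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    ids = [s.id for s in seqs]
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if p_distance(seqs[i], seqs[j]) < link_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(ids):
        groups.setdefault(find(i), []).append(name)
    clusters = [sorted(members) for members in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def call_mito(
    query: AlignedSeq,
    clade_refs: Mapping[str, Sequence[AlignedSeq]],
    margin_threshold: float = 0.02,
) -> MitoCall:
    """Assign a COI query to the haplogroup with least mean p-distance.

    The call is ``ambiguous`` when the margin between the best and
    second-best clade is below ``margin_threshold``.
    """
    if not clade_refs:
        raise ValueError("no reference clades provided")
    means: dict[str, float] = {}
    for clade, refs in clade_refs.items():
        try:
            means[clade] = group_p_distance([query], refs)
        except UndefinedDistanceError:
            continue
    if not means:
        raise UndefinedDistanceError(
            f"distance to every clade undefined for {query.id}"
        )
    ranked = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    best_clade, best = ranked[0]
    margin = (ranked[1][1] - best) if len(ranked) > 1 else float("inf")
    clade = best_clade if margin >= margin_threshold else "ambiguous"
    return MitoCall(clade=clade, mean_dist_to_best=best, margin=margin)


def compose_genotype(mito: MitoCall, nuc: NuclearCall) -> GenotypeCode:
    """Combine marker calls into the four-letter genotype code.

    For a heterozygote the maternal allele is written first, and the
    maternal species is fixed by the mitochondrial clade: clade ``a``
    gives ``AF``, clades ``f``/``f2`` give ``FA``.
    """
    if mito.clade == "ambiguous":
        raise CompositionError("mitochondrial call is ambiguous")
    if nuc.genotype == "ambiguous":
        raise CompositionError("nuclear call is ambiguous")
    if nuc.genotype == "AF":
        nuclear = ("A", "F") if mito.clade == "a" else ("F", "A")
    else:
        nuclear = (nuc.genotype[0], nuc.genotype[1])
    return GenotypeCode(mito=mito.clade, nuclear=nuclear)


def read_fasta(path, locus: str) -> list[AlignedSeq]:
    """Read a (wrapped or unwrapped) multi-FASTA into AlignedSeq records."""
    records = [
        AlignedSeq(id=rec.id, residues=str(rec.seq), locus=locus)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(path, seqs: Iterable[AlignedSeq]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")
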