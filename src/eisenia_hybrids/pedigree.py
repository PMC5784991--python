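"""Family-table parsing and hybrid census for *Eisenia* breeding pedigrees.

The laboratory breeding records are kept as a tab-separated family table:
one row per mated pair with its genotyped offspring.  Individuals are
written as genotype code plus numeric id, e.g. ``aAF96``; a worm whose
tail was re-sampled accumulates several numbers (``aAF96/103``), so
individuals are deduplicated by their numeric alias set.  Square
brackets in the offspring cell record which hatchlings were later housed
together; they are ignored for counting.

The census tallies distinct hybrid offspring (heterozygous nuclear
genotypes ``aAF`` and ``fFA``) by the cross type of their family of
birth, which exposes the asymmetry of hybridization between the two
species: ``aAF`` hybrids arise directly from interspecific pairs while
``fFA`` hybrids appear only in backcrosses of hybrids to *E. fetida*.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genotypes import GenotypeCode, GenotypeError
from .inheritance import classify_cross_type

_INDIVIDUAL_RE = re.compile(
    r"^(?P<code>(?:f2|a|f)[AF][AF])(?P<aliases>\d+(?:/\d+)*)(?P<suffix>[A-Za-z]*)$"
)

GENERATION_ORDER = {"P": 0, "F1": 1, "F2": 2, "F3": 3}


def _label_rank(label: str) -> int:
    if label == "P":
        return 0
    if label.startswith("F") and label[1:].isdigit():
        return int(label[1:])
    return 0


class PedigreeParseError(ValueError):
    """A family-table cell could not be parsed; carries row/column context."""


class PedigreeIntegrityError(ValueError):
    """Structurally impossible pedigree (e.g. an individual born twice)."""


@dataclass
class Individual:
    canonical_id: str
    genotype: GenotypeCode
    aliases: frozenset[int]
    family_of_birth: str | None = None
    generation: str = "unknown"

    def merge_aliases(self, numbers: frozenset[int]) -> None:
        self.aliases = self.aliases | numbers
        self.canonical_id = self.genotype.label + "/".join(
            str(n) for n in sorted(self.aliases)
        )


@dataclass
class Family:
    id: str
    parents: tuple[Individual, Individual]
    offspring: list[Individual]
    offspring_generation: str
    cross_type: str


@dataclass
class Pedigree:
    individuals: list[Individual] = field(default_factory=list)
    families: list[Family] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def find(self, genotype: GenotypeCode, numbers: frozenset[int]) -> Individual | None:
        """Locate an individual by genotype and numeric-alias overlap."""
        for ind in self.individuals:
            if ind.genotype == genotype and ind.aliases & numbers:
                return ind
        return None


def _parse_individual_token(token: str, row: int, column: str) -> tuple[GenotypeCode, frozenset[int]]:
    token = token.strip()
    m = _INDIVIDUAL_RE.match(token)
    if m is None:
        raise PedigreeParseError(
            f"row {row}, {column}: cannot parse individual {token!r}"
        )
    try:
        gt = GenotypeCode.from_label(m.group("code"))
    except GenotypeError as exc:  # pragma: no cover - regex pre-filters
        raise PedigreeParseError(f"row {row}, {column}: {exc}") from exc
    numbers = frozenset(int(n) for n in m.group("aliases").split("/"))
    return gt, numbers


def _resolve(
    ped: Pedigree, gt: GenotypeCode, numbers: frozenset[int]
) -> Individual:
    """Find-or-create an individual, merging alias sets on overlap and
    flagging number reuse across different genotypes."""
    existing = ped.find(gt, numbers)
    if existing is not None:
        existing.merge_aliases(numbers)
        return existing
    for other in ped.individuals:
        if other.aliases & numbers and other.genotype != gt:
            ped.flags.append(
                f"number(s) {sorted(other.aliases & numbers)} reused by "
                f"{gt.label} and {other.genotype.label}; kept distinct"
            )
    ind = Individual(
        canonical_id=gt.label + "/".join(str(n) for n in sorted(numbers)),
        genotype=gt,
        aliases=numbers,
    )
    ped.individuals.append(ind)
    return ind


def _split_offspring_cell(cell: str) -> list[str]:
    cell = cell.replace("[", "").replace("]", "").strip()
    if cell in ("", "---"):
        return []
    return [tok.strip() for tok in cell.split(";") if tok.strip() and tok.strip() != "---"]


def parse_family_table(text: str) -> Pedigree:
    """Parse a tab-separated family table into a pedigree graph.

    Expected columns: ``family_id``, ``parent1``, ``parent2``,
    ``generation`` (label of the offspring cohort), ``offspring``
    (';'-separated individual codes; ``---`` or empty means none).
    Parents are cross-referenced to earlier rows' offspring when their
    genotype and a numeric alias match.
    """
    ped = Pedigree()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"family_id", "parent1", "parent2", "generation", "offspring"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise PedigreeParseError(
            f"family table must have columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    for rownum, row in enumerate(reader, start=2):
        fam_id = row["family_id"].strip()
        parents = []
        for col in ("parent1", "parent2"):
            gt, numbers = _parse_individual_token(row[col], rownum, col)
            parents.append(_resolve(ped, gt, numbers))
        offspring = []
        for token in _split_offspring_cell(row["offspring"]):
            gt, numbers = _parse_individual_token(token, rownum, "offspring")
            child = _resolve(ped, gt, numbers)
            if child.family_of_birth is not None and child.family_of_birth != fam_id:
                raise PedigreeIntegrityError(
                    f"{child.canonical_id} recorded as offspring of both "
                    f"{child.family_of_birth} and {fam_id}"
                )
            child.family_of_birth = fam_id
            child.generation = row["generation"].strip()
            offspring.append(child)
        ped.families.append(
            Family(
                id=fam_id,
                parents=(parents[0], parents[1]),
                offspring=offspring,
                offspring_generation=row["generation"].strip(),
                cross_type=classify_cross_type(parents[0].genotype, parents[1].genotype),
            )
        )
    return ped


def generation_labels(
    pedigree: Pedigree, overrides: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Structural generation of every individual: founders are ``P`` and
    each offspring is one generation past its latest parent.

    ``overrides`` maps canonical ids to forced labels, accommodating the
    convention of re-labelling pure-species siblings used to found a new
    line as parental generation.  Raises on pedigree cycles.
    """
    overrides = dict(overrides or {})
    family_by_id = {f.id: f for f in pedigree.families}
    birth_family = {
        ind.canonical_id: family_by_id[ind.family_of_birth]
        for ind in pedigree.individuals
        if ind.family_of_birth is not None
    }
    labels: dict[str, str] = {}
    in_progress: set[str] = set()

    def rank(ind: Individual) -> int:
        cid = ind.canonical_id
        if cid in overrides:
            return _label_rank(overrides[cid])
        if cid in labels:
            return _label_rank(labels[cid])
        if cid in in_progress:
            raise PedigreeIntegrityError(f"pedigree cycle through {cid}")
        if cid not in birth_family:
            return 0
        in_progress.add(cid)
        r = 1 + max(rank(p) for p in birth_family[cid].parents)
        in_progress.discard(cid)
        return r

    inverse_order = {v: k for k, v in GENERATION_ORDER.items()}
    for ind in pedigree.individuals:
        cid = ind.canonical_id
        if cid in overrides:
            labels[cid] = overrides[cid]
        else:
            r = rank(ind)
            labels[cid] = inverse_order.get(r, f"F{r}")
    return labels


@dataclass
class HybridCensus:
    """Counts of distinct hybrid individuals by class, origin and generation."""

    n_aAF: int
    n_fFA: int
    by_origin: dict[str, dict[str, int]]
    by_generation: dict[str, dict[str, int]]
    n_fFA_in_F1_of_interspecific: int

    def asymmetry_summary(self) -> dict:
        return {
            "n_aAF": self.n_aAF,
            "n_fFA": self.n_fFA,
            "aAF_from_interspecific": self.by_origin["aAF"].get("interspecific", 0),
            "aAF_from_backcross": self.by_origin["aAF"].get("backcross", 0),
            "fFA_in_F1_of_interspecific": self.n_fFA_in_F1_of_interspecific,
        }

    def to_dict(self) -> dict:
        d = self.asymmetry_summary()
        d["by_origin"] = self.by_origin
        d["by_generation"] = self.by_generation
        return d


def hybrid_census(pedigree: Pedigree) -> HybridCensus:
    """Tally distinct hybrid offspring by genotype class, by the cross
    type of their family of birth, and by generation label."""
    family_by_id = {f.id: f for f in pedigree.families}
    by_origin: dict[str, dict[str, int]] = {"aAF": {}, "fFA": {}}
    by_generation: dict[str, dict[str, int]] = {"aAF": {}, "fFA": {}}
    n_fFA_f1_inter = 0
    counts = {"aAF": 0, "fFA": 0}
    for ind in pedigree.individuals:
        if not ind.genotype.is_hybrid or ind.family_of_birth is None:
            continue
        label = ind.genotype.label
        if label not in counts:  # e.g. f2-mito hybrids, none observed
            counts[label] = 0
            by_origin[label] = {}
            by_generation[label] = {}
        family = family_by_id[ind.family_of_birth]
        counts[label] += 1
        by_origin[label][family.cross_type] = by_origin[label].get(family.cross_type, 0) + 1
        gen = family.offspring_generation
        by_generation[label][gen] = by_generation[label].get(gen, 0) + 1
        if label == "fFA" and gen == "F1" and family.cross_type == "interspecific":
            n_fFA_f1_inter += 1
    return HybridCensus(
        n_aAF=counts["aAF"],
        n_fFA=counts["fFA"],
        by_origin=by_origin,
        by_generation=by_generation,
        n_fFA_in_F1_of_interspecific=n_fFA_f1_inter,
    )


def individuals_table(pedigree: Pedigree) -> list[dict]:
    """Flat per-individual rows for CSV export."""
    family_by_id = {f.id: f for f in pedigree.families}
    rows = []
    for ind in pedigree.individuals:
        origin = family_by_id.get(ind.family_of_birth) if ind.family_of_birth else None
        rows.append(
            {
                "canonical_id": ind.canonical_id,
                "genotype": ind.genotype.label,
                "generation": ind.generation if ind.family_of_birth else "P",
                "family_of_birth": ind.family_of_birth or "",
                "origin_cross_type": origin.cross_type if origin else "",
            }
        )
    return rows
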