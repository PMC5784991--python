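"""Gamete-inheritance model for hermaphroditic *Eisenia* matings.

Each worm produces ova carrying its mitochondrial clade plus one nuclear
allele, and sperm carrying one nuclear allele only (mitochondria are not
transmitted paternally).  An offspring's code is therefore fully
determined by one ovum and one sperm: its mitochondrial clade is the
ovum parent's, and its nuclear pair is (ovum allele, sperm allele),
maternal first.

A heterozygous worm can in principle produce "incompatible" ova whose
nuclear allele belongs to the other species than its mitochondria (an
``aF`` or ``fA`` ovum).  Such ova are considered unlikely to function
and are excluded by default; the exclusion is a policy switch, not a
hard rule.

Because every worm in a pair can both self-fertilize and be
cross-fertilized by its partner, an observed offspring genotype may be
explained by several distinct fertilization scenarios; enumerating them
is the core of pedigree consistency checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genotypes import CLADE_SPECIES_ALLELE, GenotypeCode

MODES = ("self", "facilitated_self", "cross")


@dataclass(frozen=True, order=True)
class Gamete:
    """An ovum (with mitochondria) or a sperm (nuclear allele only)."""

    kind: str  # "ovum" | "sperm"
    nuclear: str  # "A" | "F"
    mito: str | None = None  # clade for ova, None for sperm

    def __post_init__(self) -> None:
        if self.kind == "sperm" and self.mito is not None:
            raise ValueError("sperm does not transmit mitochondria")
        if self.kind == "ovum" and self.mito is None:
            raise ValueError("ovum must carry a mitochondrial clade")

    @property
    def compatible(self) -> bool:
        """True when an ovum's nuclear allele matches its mito lineage."""
        if self.kind != "ovum":
            return True
        return CLADE_SPECIES_ALLELE[self.mito] == self.nuclear


@dataclass(frozen=True)
class CompatibilityPolicy:
    """Whether to exclude mito/nuclear-mismatched ova from enumeration."""

    exclude_incompatible_ova: bool = True


DEFAULT_POLICY = CompatibilityPolicy()
PERMISSIVE_POLICY = CompatibilityPolicy(exclude_incompatible_ova=False)


@dataclass(frozen=True)
class FertilizationScenario:
    """One (mode, ovum parent, sperm parent, gametes) explanation of an
    offspring genotype.  ``facilitated_self`` marks selfing of a worm
    that had a partner present."""

    mode: str
    ovum_parent: str
    sperm_parent: str
    ovum: Gamete
    sperm: Gamete
    offspring_code: GenotypeCode

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown fertilization mode {self.mode!r}")
        selfing = self.mode in ("self", "facilitated_self")
        if selfing != (self.ovum_parent == self.sperm_parent):
            raise ValueError("mode inconsistent with parent identity")


def fertilize(ovum: Gamete, sperm: Gamete) -> GenotypeCode:
    """Offspring code from one ovum and one sperm (maternal-first)."""
    return GenotypeCode(mito=ovum.mito, nuclear=(ovum.nuclear, sperm.nuclear))


def ova_of(gt: GenotypeCode, policy: CompatibilityPolicy = DEFAULT_POLICY) -> frozenset[Gamete]:
    """Ova a worm of this genotype produces; incompatible ova dropped
    under the default policy."""
    ova = {Gamete(kind="ovum", nuclear=allele, mito=gt.mito) for allele in set(gt.nuclear)}
    if policy.exclude_incompatible_ova:
        ova = {o for o in ova if o.compatible}
    return frozenset(ova)


def sperm_of(gt: GenotypeCode) -> frozenset[Gamete]:
    """Sperm types: one per distinct nuclear allele."""
    return frozenset(Gamete(kind="sperm", nuclear=allele) for allele in set(gt.nuclear))


def offspring_codes(
    mother_gt: GenotypeCode,
    father_gt: GenotypeCode,
    mode: str = "cross",
    policy: CompatibilityPolicy = DEFAULT_POLICY,
) -> frozenset[GenotypeCode]:
    """All offspring codes from the mother's ova and the sperm source.

    ``mode="self"`` uses the mother's own sperm (``father_gt`` must then
    equal ``mother_gt``); ``mode="cross"`` uses the father's.
    """
    if mode in ("self", "facilitated_self"):
        if father_gt != mother_gt:
            raise ValueError("selfing requires identical mother and father genotypes")
        sperm_source = mother_gt
    elif mode == "cross":
        sperm_source = father_gt
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return frozenset(
        fertilize(ovum, sperm)
        for ovum in ova_of(mother_gt, policy)
        for sperm in sperm_of(sperm_source)
    )


def explain_offspring(
    pair: tuple[GenotypeCode, GenotypeCode],
    offspring_gt: GenotypeCode,
    policy: CompatibilityPolicy = DEFAULT_POLICY,
    parent_ids: tuple[str, str] = ("P1", "P2"),
) -> list[FertilizationScenario]:
    """Every fertilization scenario within a pair that yields the
    observed offspring code.  An empty list means the offspring is
    inconsistent with the pair."""
    scenarios: list[FertilizationScenario] = []
    parents = list(zip(parent_ids, pair))
    for idx, (ovum_id, ovum_gt) in enumerate(parents):
        partner_id, partner_gt = parents[1 - idx]
        for ovum in ova_of(ovum_gt, policy):
            # facilitated self: own sperm, partner present
            for sperm in sperm_of(ovum_gt):
                if fertilize(ovum, sperm) == offspring_gt:
                    scenarios.append(
                        FertilizationScenario(
                            mode="facilitated_self",
                            ovum_parent=ovum_id,
                            sperm_parent=ovum_id,
                            ovum=ovum,
                            sperm=sperm,
                            offspring_code=offspring_gt,
                        )
                    )
            for sperm in sperm_of(partner_gt):
                if fertilize(ovum, sperm) == offspring_gt:
                    scenarios.append(
                        FertilizationScenario(
                            mode="cross",
                            ovum_parent=ovum_id,
                            sperm_parent=partner_id,
                            ovum=ovum,
                            sperm=sperm,
                            offspring_code=offspring_gt,
                        )
                    )
    return scenarios


def classify_cross_type(gt1: GenotypeCode, gt2: GenotypeCode) -> str:
    """Cross type of a pair by hybrid status and nuclear species."""
    if gt1.is_hybrid and gt2.is_hybrid:
        return "hybrid_hybrid"
    if gt1.is_hybrid or gt2.is_hybrid:
        return "backcross"
    if gt1.nuclear_species == gt2.nuclear_species:
        return "intraspecific"
    return "interspecific"


@dataclass
class ConsistencyReport:
    """Per-offspring scenario lists plus summary counts for a pedigree."""

    scenarios: dict[str, list[FertilizationScenario]] = field(default_factory=dict)
    unexplained: list[str] = field(default_factory=list)

    @property
    def n_explained(self) -> int:
        return len(self.scenarios) - len(self.unexplained)

    @property
    def n_unexplained(self) -> int:
        return len(self.unexplained)


def pedigree_consistency(pedigree, policy: CompatibilityPolicy = DEFAULT_POLICY) -> ConsistencyReport:
    """Check every offspring in a pedigree against its family's parents.

    Accepts a parsed :class:`~eisenia_hybrids.pedigree.Pedigree`; flags
    offspring with no explaining fertilization scenario.
    """
    report = ConsistencyReport()
    for family in pedigree.families:
        p1, p2 = family.parents
        for child in family.offspring:
            scen = explain_offspring(
                (p1.genotype, p2.genotype),
                child.genotype,
                policy=policy,
                parent_ids=(p1.canonical_id, p2.canonical_id),
            )
            report.scenarios[child.canonical_id] = scen
            if not scen:
                report.unexplained.append(child.canonical_id)
    return report
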