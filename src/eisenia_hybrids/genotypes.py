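"""Genotype codes for the dual-marker identification of *Eisenia* worms.

Each individual is labelled by a compact code combining the maternally
inherited mitochondrial COI clade (lowercase ``a``, ``f`` or ``f2``) with
its two nuclear 28S alleles (uppercase ``A`` or ``F``), the maternal
allele written first.  ``aAA`` is a pure *E. andrei*, ``fFF`` or ``f2FF``
a pure *E. fetida*, and ``aAF`` / ``fFA`` are reciprocal interspecific
hybrids distinguished by the species of the ovum they hatched from.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

MITO_CLADES = ("a", "f", "f2")
NUCLEAR_ALLELES = ("A", "F")

#: species lineage each mitochondrial clade belongs to, keyed by clade,
#: value is the nuclear allele of that species.  f2 is a divergent
#: *E. fetida* clade, hence allele F.
CLADE_SPECIES_ALLELE = {"a": "A", "f": "F", "f2": "F"}

_CODE_RE = re.compile(r"^(f2|a|f)([AF])([AF])$")


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype labels."""


@dataclass(frozen=True, order=True)
class GenotypeCode:
    """Maternal mitochondrial clade plus ordered diploid nuclear alleles.

    Parameters
    ----------
    mito :
        Mitochondrial clade, one of ``a``, ``f``, ``f2``.
    nuclear :
        Ordered pair of 28S alleles, maternal first (e.g. ``("A", "F")``).
    """

    mito: str
    nuclear: tuple[str, str]

    def __post_init__(self) -> None:
        if self.mito not in MITO_CLADES:
            raise GenotypeError(f"unknown mitochondrial clade {self.mito!r}")
        if (
            len(self.nuclear) != 2
            or any(x not in NUCLEAR_ALLELES for x in self.nuclear)
        ):
            raise GenotypeError(f"invalid nuclear alleles {self.nuclear!r}")

    @property
    def label(self) -> str:
        return self.mito + self.nuclear[0] + self.nuclear[1]

    @property
    def is_heterozygous(self) -> bool:
        return self.nuclear[0] != self.nuclear[1]

    @property
    def is_hybrid(self) -> bool:
        """Heterozygous at the nuclear marker: an interspecific hybrid."""
        return self.is_heterozygous

    @property
    def is_pure(self) -> bool:
        """Homozygous nuclear genotype matching the mitochondrial lineage."""
        return (
            not self.is_heterozygous
            and self.nuclear[0] == CLADE_SPECIES_ALLELE[self.mito]
        )

    @property
    def nuclear_species(self) -> str | None:
        """Species of a homozygote by its nuclear alleles; None for hybrids."""
        if self.is_heterozygous:
            return None
        return self.nuclear[0]

    @classmethod
    def from_label(cls, label: str) -> "GenotypeCode":
        m = _CODE_RE.match(label)
        if m is None:
            raise GenotypeError(f"cannot parse genotype code {label!r}")
        return cls(mito=m.group(1), nuclear=(m.group(2), m.group(3)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


#: the eight syntactically valid codes (3 clades x 4 ordered allele pairs
#: collapses to 3 x 4 = 12 strings, but aFA/aAF etc. are distinct labels).
ALL_CODES: tuple[GenotypeCode, ...] = tuple(
    GenotypeCode(m, (x, y))
    for m in MITO_CLADES
    for x in NUCLEAR_ALLELES
    for y in NUCLEAR_ALLELES
)
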