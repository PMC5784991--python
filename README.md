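# eisenia-hybrids

Dual-marker hybrid detection and mating-system simulation for the
composting earthworms *Eisenia andrei* (Ea) and *E. fetida* (Ef).

Ea and Ef are simultaneous hermaphrodites capable of both reciprocal
cross-fertilization and self-fertilization, which makes the offspring of
a laboratory Ea+Ef pair genetically ambiguous: a hatchling may be a
selfed pure-species worm or an interspecific hybrid. This package
implements the standard two-marker resolution of that ambiguity and the
downstream pedigree and simulation analyses:

- **Mitochondrial COI** is maternally inherited, so a worm's haplogroup
  (`a` for *E. andrei*; `f` or the divergent `f2` for *E. fetida*)
  identifies the species of the ovum it hatched from. Haplogroups are
  assigned by uncorrected p-distance
  *p* = (mismatches) / (pairwise-comparable sites) to reference sets,
  and recovered de novo by single-linkage clustering at a distance
  threshold.
- **Nuclear 28S** is diploid and biparental. At each species-diagnostic
  alignment column (fixed base *b*<sub>A</sub> in Ea references, a
  different fixed *b*<sub>F</sub> in Ef), a query is scored hom-A,
  hom-F, or heterozygous when it carries the two-base IUPAC ambiguity
  code for {*b*<sub>A</sub>, *b*<sub>F</sub>} (a Sanger double peak).
  All-hom-A gives genotype `AA`, all-hom-F gives `FF`, and a
  predominantly heterozygous profile gives the hybrid call `AF`.
- The two calls compose into a **genotype code** — lowercase maternal
  clade, then the two nuclear alleles with the maternal allele first:
  `aAA`, `fFF`, `f2FF` for pure worms, `aAF` and `fFA` for reciprocal
  hybrids.
- A **gamete-inheritance model** enumerates each genotype's ova (which
  carry the mitochondria) and sperm (which do not), derives all
  offspring codes under selfing and crossing, and lists every
  fertilization scenario consistent with an observed offspring —
  the machinery behind pedigree consistency checking and the hybrid
  census of the breeding-experiment family table.
- A **forward mating simulator** replays the pairing experiments:
  Poisson cocoon production per worm-week, cross-type-dependent cocoon
  sterility, zero-truncated-Poisson hatchlings per viable cocoon, and
  per-ovum cross-fertilization with probability *h* versus facilitated
  selfing with 1 − *h*. The per-line hybridization rate is recovered by
  the binomial MLE ĥ = n<sub>hybrid</sub> / n<sub>total</sub> with a
  Clopper–Pearson 95% interval.

## Worked example

Genotype a simulated cohort against a simulated reference panel:

```sh
python analysis/01_simulate_sequences.py
python analysis/02_genotype.py
```

```
panel: 9 polymorphic / 7 diagnostic 28S sites; COI divergences a-f 0.152, f-f2 0.116; 50 query individuals -> results/sequences
genotyped 50 individuals: 0 call errors (0.0%) -> results/genotypes.csv
```

The panel has nine 28S columns that vary at all, of which seven are
species-diagnostic and drive the nuclear call; the three COI haplogroups
sit at mean between-group p-distances ≈ 0.15 (a vs f) and ≈ 0.114
(f vs f2), and every composed genotype code matches the generator's
truth.

Census the breeding-experiment pedigree (packaged with the library):

```sh
python analysis/03_pedigree_census.py
```

```
{
  "n_aAF": 26,
  "n_fFA": 4,
  "aAF_from_interspecific": 18,
  "aAF_from_backcross": 8,
  "fFA_in_F1_of_interspecific": 0
}
78 offspring checked, 0 unexplained; outputs in results
```

This is the asymmetric-hybridization signal: 26 `aAF` hybrids (18 born
directly to Ea+Ef pairs, 8 to backcrosses) against only 4 `fFA`
hybrids, all of which arose in backcrosses of `aAF` hybrids to `fFF`
worms and none among first-generation interspecific offspring. Every
one of the 78 genotyped offspring is explainable by at least one
fertilization scenario of its recorded parents.

The same operations are available from the command line
(`eisenia-hybrids genotype | census | scenarios | simulate | distances`),
e.g.:

```sh
eisenia-hybrids scenarios --parents aAF,aAA --offspring aAF
```

```
{"mode": "facilitated_self", "ovum_parent": "aAF", "sperm_parent": "aAF", "ovum": "aA", "sperm": "F", "offspring": "aAF"}
{"mode": "cross", "ovum_parent": "aAA", "sperm_parent": "aAF", "ovum": "aA", "sperm": "F", "offspring": "aAF"}
```

— an `aAF` offspring of a hybrid backcrossed to `aAA` cannot be
attributed to one parent without additional markers.

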