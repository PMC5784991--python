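# Methods

## Marker model

Two loci identify each worm. The mitochondrial COI fragment is
uniparentally inherited through the ovum, so its haplogroup (`a`, `f`,
`f2`) records maternal species; it cannot detect hybrids on its own.
The nuclear 28S fragment is diploid; *E. andrei* and *E. fetida*
references differ at a small set of fixed, species-diagnostic alignment
columns, and a hybrid's Sanger consensus shows both bases at each of
them. We model those double peaks as the two-base IUPAC ambiguity code
(e.g. `R` for A/G); chromatogram processing is out of scope, only
sequence text is handled.

**Site discovery.** A column is *polymorphic* when the pooled reference
set carries at least two distinct unambiguous bases (gaps, `N` and
ambiguity codes are ignored for this purpose), and *diagnostic* when
additionally all A-references are fixed for one base and all
F-references for a different one. Diagnostic sites are by construction
a subset of polymorphic sites. All coordinates are 1-based.

**Nuclear call.** Each diagnostic column scores `homA`, `homF`, `het`
(exact two-base code for the two alleles) or `unresolved`. Genotype
`AA`/`FF` requires all resolved columns to agree; `AF` requires a
heterozygous fraction ≥ 0.8 of resolved columns *and* at least 2
heterozygous columns. The threshold tolerates one miscalled peak among
seven sites; a mosaic of `homA` and `homF` without ambiguity codes is
never called `AF` — it is returned `ambiguous` as a possible
chimera/contamination signal. Zero resolved columns is a warning, not
an exception.

**Distances and haplogroups.** The uncorrected p-distance is the
mismatch fraction over columns where both sequences have unambiguous
bases (pairwise deletion, never global). Group distance is the
arithmetic mean over all between-group pairs; the alternative readings
(consensus-to-consensus, model-corrected) were considered and rejected
as less conventional for uncorrected distances. Haplogroup assignment
is argmin of mean distance to each reference clade, returned
`ambiguous` when the best-vs-second margin is below 0.02 — roughly the
within-clade noise scale and an order of magnitude below the smallest
between-clade divergence (0.114). De-novo structure uses
single-linkage clustering: connected components of the graph with
edges at distance < 0.05, a threshold sitting between observed
within-clade variation (≲ 0.02) and the f–f2 split (0.114). Ties are
broken deterministically (clusters ordered by size then lexicographic
id). This replaces maximum-likelihood phylogram inference, which is
out of scope; with clade separations this deep the partition is
insensitive to the linkage choice.

**Code composition.** The genotype code is maternal clade + ordered
nuclear pair, maternal allele first. For a heterozygote the orientation
is fixed by the mitochondria: clade `a` gives `AF`, clades `f`/`f2`
give `FA`. `f2` is treated purely as a maternal lineage whose species
allele is F (only `f2FF` worms have been observed); no separate nuclear
allele class is introduced.

## Gamete model

A worm of genotype *m*XY produces ova {*m*X, *m*Y} and sperm {X, Y};
sperm carry no mitochondria. An ovum whose allele belongs to the other
species than its mitochondria (`aF`, `fA`) is *incompatible* and is
excluded by default, since such combinations are disfavoured in related
systems; the exclusion is a `CompatibilityPolicy` switch because it is
a plausibility judgement, not an impossibility. Offspring code =
(ovum clade, ovum allele, sperm allele).

Within a pair, every offspring can arise from either worm's ova,
fertilized by own sperm (*facilitated self-fertilization* — genetically
identical to isolated selfing, distinguished only by the partner's
presence; reports use the `facilitated_self` label) or by the partner's
sperm (*cross*). `explain_offspring` enumerates all matching
(ovum parent, ovum, sperm parent, sperm) scenarios; an empty list marks
an inconsistent offspring. Viability is deliberately *not* part of the
enumeration: hybrid×hybrid pairs have enumerable offspring codes, and
their observed sterility is a simulator parameter (possibly censored
observation, not proven impossibility).

Pair cross types: both pure and same nuclear species → intraspecific
(this includes fFF+f2FF); pure different species → interspecific; one
hybrid → backcross; two hybrids → hybrid_hybrid.

## Pedigree handling

Family tables are TSV with columns `family_id`, `parent1`, `parent2`,
`generation`, `offspring` (';'-separated codes; `[...]` brackets record
co-housing and are ignored; `---` means no offspring). Individuals are
deduplicated by genotype plus numeric-alias overlap — repeated tail
sampling gives one worm several numbers (`aAF96/103`). The packaged
table reuses some bare numbers across *different* genotypes (96, 141);
these are kept as distinct worms and surfaced in `Pedigree.flags`
rather than treated as errors, since the genotypes cannot belong to one
individual. Structural impossibilities (an individual born in two
families, pedigree cycles) raise integrity errors. Founders are created
on first reference as parents.

Generations: founders are `P`, every offspring is one generation past
its latest-generation parent; an override map accommodates the breeding
convention of relabelling pure-species siblings that found a new line
as parental (packaged overrides: `aAA62`, `fFF61`). The census counts
distinct hybrid individuals by class (`aAF`, `fFA`), by the cross type
of their family of birth and by generation label. Pure-genotype totals
from the table are *not* comparable to collection-wide counts, because
pure worms unconnected to hybrids were mostly omitted from the records.

## Simulator

`simulate_pair` follows one pair for a number of weeks. Per week each
worm lays Poisson(cocoon rate) cocoons containing its own ova; a cocoon
is sterile with the arm's sterility probability; a viable cocoon yields
zero-truncated Poisson hatchlings. Each hatchling derives from one
ovum, cross-fertilized with probability `h_a` (aA ova) or `h_f` (fF
ova), else self-fertilized; gametes are drawn uniformly from the
inheritance model's enumeration, so the simulator can never emit a
genotype the model disallows.

Calibration (arm → cocoons/worm/week, sterile fraction, hatchlings per
viable cocoon): Ea+Ea 2.9 / 0.07 / 2.1; Ef+Ef 3.4 / 0.48 / 1.6; Ea+Ef
4.3 / 0.77 / 1.0. The hatchling means are derived from the measured
hatchlings/worm/week divided by viable cocoons/worm/week. Arms without
measurements borrow the nearest measured arm (backcross ← Ef+Ef,
hybrid×hybrid ← Ea+Ef). Two switches encode the observed asymmetry and
default to 0: `fFA_F1_viability` (no reciprocal hybrids among
first-generation interspecific offspring) and `hybrid_pair_fertility`
(hybrid pairs produce cocoons but no hatchlings). Both are exposed
because the underlying sterility may be censored observation. The
hybridization probabilities default to `h_a = h_f = 0.3`; no measured
value exists for them, and the default merely reproduces a realistic
mix of selfed and hybrid first-generation offspring — treat it as a
placeholder, not an estimate. Poisson/zero-truncated-Poisson forms are
modelling choices; only means are constrained by data. All randomness
flows through a single `numpy.random.Generator` passed explicitly, so
runs are byte-reproducible under a fixed seed.

The sequence generator plants exactly `n_polymorphic` 28S columns
(default 9) of which `n_diagnostic` (default 7) are fixed-different
between species; the remaining columns carry a private variant
segregating within one species, alternating species across columns
(which species carries them is unrecorded, so the choice is arbitrary
and symmetric). COI clades are planted at divergences 0.150 (a–f) and
0.114 (f–f2) on disjoint column sets of a 500-site fragment, making
both divergences exactly representable; within-clade noise defaults to
0.002 substitutions/site. Synthetic data emulate marker structure
only: no alignment error, no indel variation beyond gap handling, no
sequencing quality gradients, and hybrid consensus sequences are ideal
double peaks. Passing round-trip tests therefore demonstrates internal
consistency of caller and generator, not robustness to real
chromatogram noise.

## Estimator

For one maternal line of a pure pair, offspring are hybrid (crossed)
or pure (selfed), so ĥ = k/n is the binomial MLE with Clopper–Pearson
exact 95% bounds (scipy beta quantiles). No viability correction is
applied by default; for the f-line of an interspecific pair under
`fFA_F1_viability = 0` the estimator consequently measures the
*apparent* rate among surviving offspring. Recovery at n = 1000 over
500 replicates: |bias| < 0.002 and coverage ≈ 0.95 at h ∈ {0.1, 0.3,
0.5} (see `analysis/05_rate_estimation.py`, which recomputes this
table).

## Problem sizes and numerical notes

Default analysis sizes — 5 references per clade/species, 50-individual
query cohorts, 200 replicate experiments, 500 estimator replicates —
are the package's chosen desk-scale defaults; all are command-line
flags. Distances use exact rational arithmetic implicitly (integer
mismatch counts over integer comparable counts), so equality assertions
on planted divergences are safe. Degenerate inputs are errors with
typed exceptions (`AlignmentError`, `UndefinedDistanceError`,
`PedigreeParseError`, `PedigreeIntegrityError`) except where the domain
demands tolerance: an unexplainable offspring is a finding, an
all-missing nuclear query is an ambiguous call with a warning.

## Known limitations

- No probabilistic weighting of fertilization scenarios; without
  polymorphic microsatellites, parentage within a pair is often
  genuinely unresolvable and is reported as multiple scenarios.
- No seasonal or environmental modulation of reproduction rates.
- Sperm storage is not modelled kinetically; `h` is a per-ovum
  Bernoulli summary of whatever mixture of stored sperm applies.
- The clustering substitute for tree inference gives no branch support.
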