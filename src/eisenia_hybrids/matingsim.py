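"""Forward mating simulator and synthetic sequence generator.

This module plays the role of the wet-lab side of the study: it
generates reference/query sequence sets with the observed marker
structure (a small number of 28S polymorphic sites of which most are
species-diagnostic; three COI haplogroups at realistic divergences), and
it simulates multi-generation pairing experiments of hermaphroditic
worms with cocoon production, cross-type-dependent cocoon sterility and
the observed one-sided inviability of ``fFA`` first-generation hybrids.

Reproductive parameters default to the calibration measured in the
breeding experiment: cocoon output per worm-week of 2.9 (Ea+Ea), 3.4
(Ef+Ef) and 4.3 (Ea+Ef), with sterile-cocoon fractions 0.07, 0.48 and
0.77 respectively.  Cocoon counts are Poisson and hatchlings per viable
cocoon zero-truncated Poisson; only the means are constrained by the
data, the distributional forms are modelling choices.

A binomial maximum-likelihood estimator recovers the per-ovum
cross-fertilization (hybridization) probability from offspring genotype
counts grouped by maternal line, with a Clopper-Pearson interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genotypes import CLADE_SPECIES_ALLELE, GenotypeCode
from .inheritance import (
    CompatibilityPolicy,
    DEFAULT_POLICY,
    classify_cross_type,
    fertilize,
    ova_of,
    sperm_of,
)
from .markers import PAIR_TO_IUPAC, AlignedSeq

BASES = np.array(list("ACGT"))

#: arm keys: intraspecific pairs split by species, others by cross type
ARM_KEYS = ("intra_a", "intra_f", "inter", "backcross", "hybrid_hybrid")


class ParameterError(ValueError):
    """Infeasible generator or simulator parameters."""


def arm_key(gt1: GenotypeCode, gt2: GenotypeCode) -> str:
    """Reproductive-parameter key for a pair of genotypes."""
    ct = classify_cross_type(gt1, gt2)
    if ct == "intraspecific":
        return "intra_a" if gt1.nuclear_species == "A" else "intra_f"
    if ct == "interspecific":
        return "inter"
    return ct


# ---------------------------------------------------------------------------
# synthetic sequence generation


@dataclass(frozen=True)
class SeqGenParams:
    """Shape of the synthetic marker panels.

    Defaults plant 9 polymorphic 28S columns of which 7 are
    species-diagnostic, and COI haplogroups at uncorrected divergences
    0.150 (a vs f) and 0.114 (f vs f2).  ``len_coi`` of 500 makes both
    planted divergences exactly representable as site counts.
    """

    len_coi: int = 500
    len_28s: int = 400
    n_polymorphic: int = 9
    n_diagnostic: int = 7
    div_a_f: float = 0.150
    div_f_f2: float = 0.114
    within_clade_rate: float = 0.002
    n_refs_per_clade: int = 5
    n_refs_per_species: int = 5

    def validate(self) -> None:
        if self.n_diagnostic > self.n_polymorphic:
            raise ParameterError("n_diagnostic cannot exceed n_polymorphic")
        if self.n_polymorphic > self.len_28s:
            raise ParameterError("more polymorphic sites than 28S columns")
        if not (0 <= self.div_a_f <= 1 and 0 <= self.div_f_f2 <= 1):
            raise ParameterError("divergences must be fractions in [0, 1]")
        needed = round(self.len_coi * self.div_a_f) + round(self.len_coi * self.div_f_f2)
        if needed > self.len_coi:
            raise ParameterError("planted COI divergences exceed sequence length")


@dataclass
class PanelTruth:
    """Ground truth recorded while generating a reference panel."""

    polymorphic_columns: list[int]
    diagnostic_columns: list[int]
    diagnostic_alleles: dict[int, tuple[str, str]]  # column -> (A, F)
    div_a_f: float
    div_f_f2: float
    coi_centroids: dict[str, str]  # clade -> noiseless sequence
    s28_species_seqs: dict[str, str]  # "A"/"F" -> noiseless sequence


@dataclass
class ReferencePanel:
    coi_clades: dict[str, list[AlignedSeq]]
    refs_28s_A: list[AlignedSeq]
    refs_28s_F: list[AlignedSeq]
    truth: PanelTruth


def _mutate(seq: np.ndarray, columns: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Replace the base at each (0-based) column with a different one."""
    out = seq.copy()
    for col in columns:
        choices = BASES[BASES != out[col]]
        out[col] = rng.choice(choices)
    return out


def _add_noise(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    return _mutate(seq, hits, rng)


def generate_reference_panel(
    params: SeqGenParams, rng: np.random.Generator
) -> ReferencePanel:
    """Generate COI haplogroup references and 28S species references with
    planted polymorphic/diagnostic structure, plus the ground truth."""
    params.validate()
    # --- 28S: diagnostic + within-species polymorphic columns ------------
    anc28 = rng.choice(BASES, size=params.len_28s)
    cols = rng.choice(params.len_28s, size=params.n_polymorphic, replace=False)
    diag_cols = sorted(int(c) for c in cols[: params.n_diagnostic])
    extra_cols = sorted(int(c) for c in cols[params.n_diagnostic :])
    seq_A = anc28.copy()
    seq_F = _mutate(anc28, diag_cols, rng)
    refs_A = [seq_A.copy() for _ in range(params.n_refs_per_species)]
    refs_F = [seq_F.copy() for _ in range(params.n_refs_per_species)]
    # non-diagnostic polymorphism: a private variant segregating within
    # one species (alternating species across the extra columns)
    for i, col in enumerate(extra_cols):
        carrier = refs_A if i % 2 == 0 else refs_F
        alt = rng.choice(BASES[BASES != anc28[col]])
        for ref in carrier[: max(1, len(carrier) // 2)]:
            ref[col] = alt
    diagnostic_alleles = {
        col + 1: (str(seq_A[col]), str(seq_F[col])) for col in diag_cols
    }
    # --- COI: three clades at planted divergences -------------------------
    anc_coi = rng.choice(BASES, size=params.len_coi)
    n_af = round(params.len_coi * params.div_a_f)
    n_ff2 = round(params.len_coi * params.div_f_f2)
    all_cols = rng.permutation(params.len_coi)
    cols_af = all_cols[:n_af]
    cols_ff2 = all_cols[n_af : n_af + n_ff2]  # disjoint: divergences additive
    seq_a = anc_coi.copy()
    seq_f = _mutate(anc_coi, cols_af, rng)
    seq_f2 = _mutate(seq_f, cols_ff2, rng)
    centroids = {"a": seq_a, "f": seq_f, "f2": seq_f2}
    coi_clades = {
        clade: [
            AlignedSeq(
                id=f"{clade}_ref{i}",
                residues="".join(_add_noise(base, params.within_clade_rate, rng)),
                locus="COI",
            )
            for i in range(params.n_refs_per_clade)
        ]
        for clade, base in centroids.items()
    }
    truth = PanelTruth(
        polymorphic_columns=sorted(c + 1 for c in list(diag_cols) + extra_cols),
        diagnostic_columns=[c + 1 for c in diag_cols],
        diagnostic_alleles=diagnostic_alleles,
        div_a_f=n_af / params.len_coi,
        div_f_f2=n_ff2 / params.len_coi,
        coi_centroids={k: "".join(v) for k, v in centroids.items()},
        s28_species_seqs={"A": "".join(seq_A), "F": "".join(seq_F)},
    )
    return ReferencePanel(
        coi_clades=coi_clades,
        refs_28s_A=[
            AlignedSeq(id=f"A_ref{i}", residues="".join(r), locus="28S")
            for i, r in enumerate(refs_A)
        ],
        refs_28s_F=[
            AlignedSeq(id=f"F_ref{i}", residues="".join(r), locus="28S")
            for i, r in enumerate(refs_F)
        ],
        truth=truth,
    )


def generate_individuals(
    panel: ReferencePanel,
    codes: Sequence[GenotypeCode],
    rng: np.random.Generator,
    noise_rate: float = 0.0,
) -> list[tuple[str, GenotypeCode, AlignedSeq, AlignedSeq]]:
    """Synthesise (id, truth code, COI seq, 28S seq) query records.

    The COI sequence is the individual's clade centroid; the 28S
    sequence is the species sequence for homozygotes, or the A-species
    backbone with two-base IUPAC ambiguity codes at every diagnostic
    column for heterozygotes (a Sanger-style consensus).  ``noise_rate``
    adds random substitutions to the COI sequence only.
    """
    truth = panel.truth
    out = []
    for i, code in enumerate(codes):
        name = f"{code.label}{i + 1}"
        coi = np.array(list(truth.coi_centroids[code.mito]))
        coi = _add_noise(coi, noise_rate, rng)
        if code.is_heterozygous:
            s28 = list(truth.s28_species_seqs["A"])
            for col, (a, f) in truth.diagnostic_alleles.items():
                s28[col - 1] = PAIR_TO_IUPAC[frozenset({a, f})]
            s28 = "".join(s28)
        else:
            s28 = truth.s28_species_seqs[code.nuclear[0]]
        out.append(
            (
                name,
                code,
                AlignedSeq(id=name, residues="".join(coi), locus="COI"),
                AlignedSeq(id=name, residues=s28, locus="28S"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# forward mating simulation


def _per_arm(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(ARM_KEYS) - set(value)
        if missing:
            raise ParameterError(f"missing arm keys: {sorted(missing)}")
        return dict(value)
    return {k: float(value) for k in ARM_KEYS}


@dataclass
class SimParams:
    """Reproductive and genetic parameters of the pairing simulator.

    Rates are per cross-type arm; scalars are broadcast to all arms.
    ``h_a`` / ``h_f`` are the probabilities that an ``aA`` / ``fF`` ovum
    of a paired worm is cross-fertilized by the partner rather than
    self-fertilized (facilitated selfing).  ``fFA_F1_viability`` and
    ``hybrid_pair_fertility`` default to 0, encoding the observed
    asymmetry: no ``fFA`` hybrids among first-generation interspecific
    offspring and no hatchlings from hybrid-hybrid pairs.
    """

    cocoon_rate: dict[str, float] = field(
        default_factory=lambda: {
            "intra_a": 2.9,
            "intra_f": 3.4,
            "inter": 4.3,
            "backcross": 3.4,
            "hybrid_hybrid": 4.3,
        }
    )
    sterility_prob: dict[str, float] = field(
        default_factory=lambda: {
            "intra_a": 0.07,
            "intra_f": 0.48,
            "inter": 0.77,
            "backcross": 0.48,
            "hybrid_hybrid": 0.77,
        }
    )
    hatchlings_per_viable_cocoon: dict[str, float] = field(
        default_factory=lambda: {
            "intra_a": 2.1,
            "intra_f": 1.6,
            "inter": 1.0,
            "backcross": 1.6,
            "hybrid_hybrid": 1.0,
        }
    )
    h_a: float = 0.3
    h_f: float = 0.3
    fFA_F1_viability: float = 0.0
    hybrid_pair_fertility: float = 0.0
    weeks: int = 2
    policy: CompatibilityPolicy = DEFAULT_POLICY

    def __post_init__(self) -> None:
        self.cocoon_rate = _per_arm(self.cocoon_rate)
        self.sterility_prob = _per_arm(self.sterility_prob)
        self.hatchlings_per_viable_cocoon = _per_arm(self.hatchlings_per_viable_cocoon)
        for p in (self.h_a, self.h_f, self.fFA_F1_viability, self.hybrid_pair_fertility):
            if not 0 <= p <= 1:
                raise ParameterError(f"probability out of [0, 1]: {p}")
        for d in (self.sterility_prob,):
            for k, v in d.items():
                if not 0 <= v <= 1:
                    raise ParameterError(f"sterility_prob[{k}] out of [0, 1]")
        for d in (self.cocoon_rate, self.hatchlings_per_viable_cocoon):
            for k, v in d.items():
                if v < 0:
                    raise ParameterError(f"negative rate for arm {k}")

    def with_overrides(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class CocoonRecord:
    week: int
    layer: int  # 0 or 1: which worm of the pair laid it
    sterile: bool
    n_hatchlings: int


@dataclass
class Offspring:
    code: GenotypeCode
    mode: str  # "facilitated_self" | "cross"
    ovum_parent: int  # index of the laying worm


@dataclass
class PairResult:
    genotypes: tuple[GenotypeCode, GenotypeCode]
    arm: str
    cocoons: list[CocoonRecord]
    offspring: list[Offspring]

    @property
    def n_cocoons(self) -> int:
        return len(self.cocoons)

    @property
    def n_sterile(self) -> int:
        return sum(c.sterile for c in self.cocoons)


def _zero_truncated_poisson(mean: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 1
    while True:
        k = rng.poisson(mean)
        if k >= 1:
            return int(k)


def _hybridization_prob(ovum_mito: str, params: SimParams) -> float:
    return params.h_a if ovum_mito == "a" else params.h_f


def simulate_pair(
    gt1: GenotypeCode,
    gt2: GenotypeCode,
    params: SimParams,
    rng: np.random.Generator,
) -> PairResult:
    """Simulate one pair of worms for ``params.weeks`` weeks.

    Each worm lays Poisson(cocoon rate) cocoons per week containing its
    own ova.  A cocoon is sterile with the arm's sterility probability;
    hybrid-hybrid pairs additionally yield hatchlings only with
    probability ``hybrid_pair_fertility`` per surviving cocoon.  Each
    hatchling derives from one ovum of the laying worm, fertilized by
    partner sperm with probability ``h`` (cross) or own sperm otherwise
    (facilitated self); genotypes follow the gamete-inheritance model.
    ``fFA`` offspring of interspecific pairs survive with probability
    ``fFA_F1_viability``.
    """
    arm = arm_key(gt1, gt2)
    pair = (gt1, gt2)
    cocoons: list[CocoonRecord] = []
    offspring: list[Offspring] = []
    for week in range(1, params.weeks + 1):
        for layer in (0, 1):
            mother = pair[layer]
            partner = pair[1 - layer]
            ova_types = sorted(ova_of(mother, params.policy))
            for _ in range(rng.poisson(params.cocoon_rate[arm])):
                sterile = rng.random() < params.sterility_prob[arm]
                n_hatch = 0
                if not sterile:
                    hatches = True
                    if arm == "hybrid_hybrid":
                        hatches = rng.random() < params.hybrid_pair_fertility
                    if hatches and ova_types:
                        n_hatch = _zero_truncated_poisson(
                            params.hatchlings_per_viable_cocoon[arm], rng
                        )
                cocoons.append(
                    CocoonRecord(week=week, layer=layer, sterile=sterile, n_hatchlings=n_hatch)
                )
                for _ in range(n_hatch):
                    ovum = ova_types[rng.integers(len(ova_types))]
                    crossed = rng.random() < _hybridization_prob(ovum.mito, params)
                    sperm_pool = sorted(sperm_of(partner if crossed else mother))
                    sperm = sperm_pool[rng.integers(len(sperm_pool))]
                    code = fertilize(ovum, sperm)
                    if (
                        arm == "inter"
                        and code.label == "fFA"
                        and rng.random() >= params.fFA_F1_viability
                    ):
                        continue
                    offspring.append(
                        Offspring(
                            code=code,
                            mode="cross" if crossed else "facilitated_self",
                            ovum_parent=layer,
                        )
                    )
    return PairResult(genotypes=pair, arm=arm, cocoons=cocoons, offspring=offspring)


@dataclass(frozen=True)
class Arm:
    """One design arm: a pair genotype combination replicated n_pairs times."""

    name: str
    gt1: GenotypeCode
    gt2: GenotypeCode
    n_pairs: int


#: the breeding experiment's design: 4 Ea+Ea, 4 Ef+Ef and 7 Ea+Ef pairs
DEFAULT_DESIGN = (
    Arm("Ea+Ea", GenotypeCode.from_label("aAA"), GenotypeCode.from_label("aAA"), 4),
    Arm("Ef+Ef", GenotypeCode.from_label("fFF"), GenotypeCode.from_label("fFF"), 4),
    Arm("Ea+Ef", GenotypeCode.from_label("aAA"), GenotypeCode.from_label("fFF"), 7),
)


@dataclass
class ArmSummary:
    name: str
    n_pairs: int
    cocoons_per_worm_week: float
    hatchlings_per_worm_week: float
    pct_sterile_cocoons: float
    pairs_without_offspring: int


@dataclass
class ExperimentResult:
    summaries: list[ArmSummary]
    pair_results: dict[str, list[PairResult]]
    pedigree_tsv: str

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(s) for s in self.summaries])


def simulate_experiment(
    design: Sequence[Arm],
    params: SimParams,
    rng: np.random.Generator,
) -> ExperimentResult:
    """Run every arm of a pairing design and summarise it per arm, with
    the resulting one-generation pedigree in the family-table dialect."""
    summaries = []
    pair_results: dict[str, list[PairResult]] = {}
    ped_lines = ["family_id\tparent1\tparent2\tgeneration\toffspring"]
    uid = 0
    for arm in design:
        results = [
            simulate_pair(arm.gt1, arm.gt2, params, rng) for _ in range(arm.n_pairs)
        ]
        pair_results[arm.name] = results
        worm_weeks = 2 * arm.n_pairs * params.weeks
        n_coc = sum(r.n_cocoons for r in results)
        n_ster = sum(r.n_sterile for r in results)
        n_hatch = sum(len(r.offspring) for r in results)
        summaries.append(
            ArmSummary(
                name=arm.name,
                n_pairs=arm.n_pairs,
                cocoons_per_worm_week=n_coc / worm_weeks,
                hatchlings_per_worm_week=n_hatch / worm_weeks,
                pct_sterile_cocoons=100.0 * n_ster / n_coc if n_coc else 0.0,
                pairs_without_offspring=sum(not r.offspring for r in results),
            )
        )
        for k, res in enumerate(results):
            p1 = f"{arm.gt1.label}{uid + 1}"
            p2 = f"{arm.gt2.label}{uid + 2}"
            uid += 2
            kids = []
            for off in res.offspring:
                uid += 1
                kids.append(f"{off.code.label}{uid}")
            ped_lines.append(
                f"{arm.name}-{k + 1}\t{p1}\t{p2}\tF1\t{'; '.join(kids) if kids else '---'}"
            )
    return ExperimentResult(
        summaries=summaries,
        pair_results=pair_results,
        pedigree_tsv="\n".join(ped_lines) + "\n",
    )


def simulate_maternal_line(
    mother: GenotypeCode,
    father: GenotypeCode,
    h: float,
    n: int,
    rng: np.random.Generator,
    policy: CompatibilityPolicy = DEFAULT_POLICY,
) -> list[GenotypeCode]:
    """Offspring codes of ``n`` ova of one worm in a pair.

    Each ovum is cross-fertilized by the partner with probability ``h``,
    else self-fertilized; gametes are drawn through the inheritance
    model.  This is the reduced simulation used for estimator recovery
    studies, skipping cocoon/viability bookkeeping.
    """
    ova_types = sorted(ova_of(mother, policy))
    if not ova_types:
        raise ParameterError(f"{mother.label} produces no ova under this policy")
    out = []
    for _ in range(n):
        ovum = ova_types[rng.integers(len(ova_types))]
        source = father if rng.random() < h else mother
        sperm_pool = sorted(sperm_of(source))
        sperm = sperm_pool[rng.integers(len(sperm_pool))]
        out.append(fertilize(ovum, sperm))
    return out


# ---------------------------------------------------------------------------
# hybridization-rate estimation


class EstimateUndefinedError(ValueError):
    """No informative offspring in the requested maternal line."""


@dataclass
class RateEstimate:
    h_hat: float
    ci_low: float
    ci_high: float
    n_offspring: int


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def estimate_hybridization_rate(
    offspring_codes: Sequence[GenotypeCode],
    maternal_clade: str = "a",
    alpha: float = 0.05,
) -> RateEstimate:
    """Binomial MLE of the cross-fertilization probability of one
    maternal line of a pure-species pair.

    Offspring of the ``a``-line of an interspecific pair are ``aAF``
    (cross-fertilized) or ``aAA`` (facilitated self), so
    ``h_hat = n_hybrid / n_total`` for that line; analogously for the
    ``f``-line.  No viability correction is applied.
    """
    line = [c for c in offspring_codes if c.mito == maternal_clade]
    n = len(line)
    if n == 0:
        raise EstimateUndefinedError(
            f"no offspring with maternal clade {maternal_clade!r}"
        )
    k = sum(c.is_hybrid for c in line)
    low, high = clopper_pearson(k, n, alpha)
    return RateEstimate(h_hat=k / n, ci_low=low, ci_high=high, n_offspring=n)
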