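"""Dual-marker hybrid detection and mating-system simulation for the
composting earthworms *Eisenia andrei* and *E. fetida*.

The package genotypes worms from aligned COI (mitochondrial, maternal)
and 28S (nuclear, diploid) sequences, composes the four-letter genotype
codes used to label individuals (``aAA``, ``fFF``, ``aAF``, ``fFA``,
``f2FF``), models gamete inheritance in hermaphroditic pairs, parses
breeding-experiment family tables into pedigrees with a hybrid census,
and simulates the mating experiments forward with calibrated
reproductive parameters.
"""

from importlib import resources

from .genotypes import ALL_CODES, GenotypeCode, GenotypeError
from .markers import (
    AlignedSeq,
    AlignmentError,
    CompositionError,
    DiagnosticSite,
    MarkerPanel,
    MitoCall,
    NuclearCall,
    UndefinedDistanceError,
    call_mito,
    call_nuclear,
    cluster_sequences,
    compose_genotype,
    find_diagnostic_sites,
    find_polymorphic_sites,
    group_p_distance,
    p_distance,
    read_fasta,
    write_fasta,
)
from .inheritance import (
    DEFAULT_POLICY,
    PERMISSIVE_POLICY,
    CompatibilityPolicy,
    FertilizationScenario,
    Gamete,
    classify_cross_type,
    explain_offspring,
    fertilize,
    offspring_codes,
    ova_of,
    pedigree_consistency,
    sperm_of,
)
from .pedigree import (
    Family,
    HybridCensus,
    Individual,
    Pedigree,
    PedigreeIntegrityError,
    PedigreeParseError,
    generation_labels,
    hybrid_census,
    individuals_table,
    parse_family_table,
)
from .matingsim import (
    Arm,
    DEFAULT_DESIGN,
    ExperimentResult,
    RateEstimate,
    ReferencePanel,
    SeqGenParams,
    SimParams,
    estimate_hybridization_rate,
    generate_individuals,
    generate_reference_panel,
    simulate_experiment,
    simulate_maternal_line,
    simulate_pair,
)

__version__ = "0.1.0"

#: generation-label overrides used with the packaged family table: the
#: pure-species siblings aAA62 and fFF61 founded a new line and are
#: treated as parental generation despite being first-generation born.
PACKAGED_GENERATION_OVERRIDES = {"aAA62": "P", "fFF61": "P"}


def load_packaged_family_table() -> str:
    """Text of the packaged breeding-experiment family table."""
    return (
        resources.files("eisenia_hybrids") / "data" / "family_table.tsv"
    ).read_text()


def load_packaged_pedigree() -> Pedigree:
    """The packaged breeding-experiment pedigree, parsed."""
    return parse_family_table(load_packaged_family_table())
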