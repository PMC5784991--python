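"""Diagnostic-site discovery, marker calling, p-distance and clustering."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import eisenia_hybrids as eh
from eisenia_hybrids.markers import PAIR_TO_IUPAC

from conftest import seqs


# ---------------------------------------------------------------------------
# polymorphic / diagnostic site discovery


def test_no_variation_gives_no_polymorphic_sites():
    a = seqs("28S", a1="ACGTACGT")
    f = seqs("28S", f1="ACGTACGT")
    assert eh.find_polymorphic_sites(a, f) == []
    assert eh.find_diagnostic_sites(a, f) == []


def test_single_substitution_is_polymorphic_and_diagnostic():
    a = seqs("28S", a1="ACGT")
    f = seqs("28S", f1="ACTT")
    assert eh.find_polymorphic_sites(a, f) == [3]
    (site,) = eh.find_diagnostic_sites(a, f)
    assert (site.column, site.allele_A, site.allele_F) == (3, "G", "T")


def test_within_species_polymorphism_is_not_diagnostic():
    # column 2 varies inside species A, column 4 is fixed-different
    a = seqs("28S", a1="ACGT", a2="AGGT")
    f = seqs("28S", f1="ACGA", f2="ACGA")
    assert eh.find_polymorphic_sites(a, f) == [2, 4]
    assert [s.column for s in eh.find_diagnostic_sites(a, f)] == [4]


def test_gaps_and_ambiguity_ignored_in_site_discovery():
    a = seqs("28S", a1="A-GT", a2="ANGT")
    f = seqs("28S", f1="ARGT")
    assert eh.find_polymorphic_sites(a, f) == []


def test_length_mismatch_raises_alignment_error():
    with pytest.raises(eh.AlignmentError):
        eh.find_polymorphic_sites(seqs("28S", a="ACGT"), seqs("28S", f="ACG"))
    with pytest.raises(ValueError):
        eh.find_diagnostic_sites([], seqs("28S", f="ACGT"))


def test_planted_panel_sites_recovered(default_panel, default_marker_panel):
    """Generator truth (9 polymorphic / 7 diagnostic columns) is recovered
    exactly by the detectors."""
    truth = default_panel.truth
    assert default_marker_panel.polymorphic_sites == truth.polymorphic_columns
    assert [s.column for s in default_marker_panel.diagnostic_sites] == truth.diagnostic_columns
    for site in default_marker_panel.diagnostic_sites:
        assert (site.allele_A, site.allele_F) == truth.diagnostic_alleles[site.column]
    assert len(default_marker_panel.polymorphic_sites) == 9
    assert len(default_marker_panel.diagnostic_sites) == 7


def test_diagnostic_sites_subset_of_polymorphic_random_panels():
    rng = np.random.default_rng(42)
    for _ in range(25):
        params = eh.SeqGenParams(
            len_28s=80,
            n_polymorphic=int(rng.integers(2, 12)),
            n_diagnostic=int(rng.integers(1, 3)),
        )
        params = eh.SeqGenParams(
            len_28s=80,
            n_polymorphic=max(params.n_polymorphic, params.n_diagnostic),
            n_diagnostic=params.n_diagnostic,
        )
        panel = eh.generate_reference_panel(params, rng)
        mp = eh.MarkerPanel.build(panel.refs_28s_A, panel.refs_28s_F)
        diag_cols = {s.column for s in mp.diagnostic_sites}
        assert diag_cols <= set(mp.polymorphic_sites)


# ---------------------------------------------------------------------------
# nuclear calls


def _het_query(panel, marker_panel, unresolved_at=()):
    base = list(panel.truth.s28_species_seqs["A"])
    for site in marker_panel.diagnostic_sites:
        if site.column in unresolved_at:
            base[site.column - 1] = "N"
        else:
            base[site.column - 1] = PAIR_TO_IUPAC[frozenset({site.allele_A, site.allele_F})]
    return eh.AlignedSeq(id="q", residues="".join(base), locus="28S")


def test_pure_reference_calls_are_homozygous(default_panel, default_marker_panel):
    for ref in default_panel.refs_28s_A:
        assert eh.call_nuclear(ref, default_marker_panel).genotype == "AA"
    for ref in default_panel.refs_28s_F:
        assert eh.call_nuclear(ref, default_marker_panel).genotype == "FF"


def test_full_heterozygote_called_AF(default_panel, default_marker_panel):
    call = eh.call_nuclear(_het_query(default_panel, default_marker_panel), default_marker_panel)
    assert call.genotype == "AF"
    assert call.n_het == 7
    assert call.n_resolved == 7


def test_het_with_unresolved_sites_still_AF(default_panel, default_marker_panel):
    """5 het + 2 N sites: het fraction among resolved is 1.0 >= 0.8."""
    cols = [s.column for s in default_marker_panel.diagnostic_sites][:2]
    call = eh.call_nuclear(
        _het_query(default_panel, default_marker_panel, unresolved_at=cols),
        default_marker_panel,
    )
    assert call.genotype == "AF"
    assert call.n_het == 5
    assert call.n_resolved == 5


def test_mixed_homozygous_pattern_is_ambiguous(default_panel, default_marker_panel):
    """homA/homF mosaic without ambiguity codes flags possible chimerism."""
    base = list(panel_seq := default_panel.truth.s28_species_seqs["A"])
    first = default_marker_panel.diagnostic_sites[0]
    base[first.column - 1] = first.allele_F
    call = eh.call_nuclear(
        eh.AlignedSeq(id="q", residues="".join(base), locus="28S"), default_marker_panel
    )
    assert call.genotype == "ambiguous"


def test_zero_resolved_sites_warns_not_raises(default_marker_panel, default_panel):
    q = eh.AlignedSeq(
        id="q", residues="N" * len(default_panel.refs_28s_A[0].residues), locus="28S"
    )
    with pytest.warns(UserWarning):
        call = eh.call_nuclear(q, default_marker_panel)
    assert call.genotype == "ambiguous"
    assert call.n_resolved == 0


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_by_definition():
    s1, s2 = seqs("COI", x="ACGTACGTACGTACGTACGT", y="ACGTACGTACGTACGTACGT")
    assert eh.p_distance(s1, s2) == 0.0
    # 3 mismatches over 20 comparable columns
    s3 = eh.AlignedSeq(id="z", residues="TCGTACGTACCTACGTACGA", locus="COI")
    assert eh.p_distance(s1, s3) == pytest.approx(0.15)


def test_p_distance_pairwise_deletion():
    s1, s2 = seqs("COI", x="ACGTN-", y="ANGA--")
    # columns 1, 3, 4 comparable; one mismatch (T vs A)
    assert eh.p_distance(s1, s2) == pytest.approx(1 / 3)


def test_p_distance_errors():
    s1, s2 = seqs("COI", x="NNNN", y="ACGT")
    with pytest.raises(eh.UndefinedDistanceError):
        eh.p_distance(s1, s2)
    with pytest.raises(eh.AlignmentError):
        eh.p_distance(
            eh.AlignedSeq("a", "ACGT", "COI"), eh.AlignedSeq("b", "ACGT", "28S")
        )


@given(
    st.lists(
        st.sampled_from("ACGTN-"), min_size=10, max_size=40
    ).flatmap(
        lambda tpl: st.tuples(
            st.just(tpl),
            st.lists(st.sampled_from("ACGTN-"), min_size=len(tpl), max_size=len(tpl)),
        )
    )
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_p_distance_symmetric_bounded(pair):
    r1, r2 = "".join(pair[0]), "".join(pair[1])
    s1 = eh.AlignedSeq("s1", r1, "COI")
    s2 = eh.AlignedSeq("s2", r2, "COI")
    try:
        d12 = eh.p_distance(s1, s2)
    except eh.UndefinedDistanceError:
        return
    assert d12 == eh.p_distance(s2, s1)
    assert 0.0 <= d12 <= 1.0
    assert eh.p_distance(s1, s1) == 0.0


# ---------------------------------------------------------------------------
# clustering


def _oracle_partition(sequences, threshold):
    """Independent single-linkage oracle: connected components of the
    thresholded distance graph."""
    g = nx.Graph()
    g.add_nodes_from(s.id for s in sequences)
    for i, s1 in enumerate(sequences):
        for s2 in sequences[i + 1 :]:
            if eh.p_distance(s1, s2) < threshold:
                g.add_edge(s1.id, s2.id)
    return sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: (-len(c), c[0])
    )


def test_identical_set_is_one_cluster():
    s = seqs("COI", a="ACGT", b="ACGT", c="ACGT")
    assert eh.cluster_sequences(s, 0.05) == [["a", "b", "c"]]


def test_cluster_matches_connected_components_oracle():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for trial in range(30):
        n = int(rng.integers(2, 13))
        length = 30
        raw = rng.choice(bases, size=(n, length))
        # make some sequences near-copies of others to create clusters
        for i in range(1, n):
            if rng.random() < 0.5:
                j = int(rng.integers(i))
                raw[i] = raw[j].copy()
                k = int(rng.integers(0, 4))
                for col in rng.choice(length, size=k, replace=False):
                    raw[i, col] = rng.choice(bases)
        sequences = [
            eh.AlignedSeq(f"s{i:02d}", "".join(row), "COI") for i, row in enumerate(raw)
        ]
        threshold = float(rng.choice([0.05, 0.1, 0.2]))
        assert eh.cluster_sequences(sequences, threshold) == _oracle_partition(
            sequences, threshold
        )


def test_three_planted_haplogroups_cluster_separately(default_panel):
    pool = [s for refs in default_panel.coi_clades.values() for s in refs]
    clusters = eh.cluster_sequences(pool, link_threshold=0.05)
    assert len(clusters) == 3
    for cluster in clusters:
        prefixes = {name.split("_")[0] for name in cluster}
        assert len(prefixes) == 1


# ---------------------------------------------------------------------------
# mito calls and genotype composition


def test_mito_call_exact_reference_match(default_panel):
    ref = default_panel.coi_clades["a"][0]
    call = eh.call_mito(ref, default_panel.coi_clades)
    assert call.clade == "a"
    assert call.mean_dist_to_best < 0.01


def test_mito_call_recovers_generated_f2(default_panel):
    q = eh.AlignedSeq("q", default_panel.truth.coi_centroids["f2"], "COI")
    assert eh.call_mito(q, default_panel.coi_clades).clade == "f2"


def test_equidistant_query_is_ambiguous():
    refs = {
        "a": seqs("COI", a1="AAAA"),
        "f": seqs("COI", f1="TTTT"),
    }
    q = eh.AlignedSeq("q", "AATT", "COI")
    call = eh.call_mito(q, refs)
    assert call.clade == "ambiguous"
    assert call.margin == 0.0


def test_compose_genotype_conventions():
    def mito(clade):
        return eh.MitoCall(clade=clade, mean_dist_to_best=0.0, margin=1.0)

    def nuc(gt, n_het=0):
        return eh.NuclearCall(genotype=gt, per_site={}, n_het=n_het, n_resolved=7)

    assert eh.compose_genotype(mito("a"), nuc("AA")).label == "aAA"
    assert eh.compose_genotype(mito("a"), nuc("AF", 7)).label == "aAF"
    assert eh.compose_genotype(mito("f"), nuc("AF", 7)).label == "fFA"
    assert eh.compose_genotype(mito("f2"), nuc("FF")).label == "f2FF"
    with pytest.raises(eh.CompositionError, match="mitochondrial"):
        eh.compose_genotype(mito("ambiguous"), nuc("AA"))
    with pytest.raises(eh.CompositionError, match="nuclear"):
        eh.compose_genotype(mito("a"), nuc("ambiguous"))


def test_sequence_label_round_trip_zero_noise(default_panel, default_marker_panel):
    """Generator truth is recovered with zero errors at zero added noise."""
    rng = np.random.default_rng(5)
    labels = ["aAA", "fFF", "f2FF", "aAF", "fFA"] * 4
    codes = [eh.GenotypeCode.from_label(l) for l in labels]
    for name, code, coi, s28 in eh.generate_individuals(default_panel, codes, rng):
        m = eh.call_mito(coi, default_panel.coi_clades)
        n = eh.call_nuclear(s28, default_marker_panel)
        assert eh.compose_genotype(m, n).label == code.label
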