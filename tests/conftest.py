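import numpy as np
import pytest

import eisenia_hybrids as eh


def seqs(locus, **named):
    """Build AlignedSeq records from id=residues keyword pairs."""
    return [eh.AlignedSeq(id=k, residues=v, locus=locus) for k, v in named.items()]


@pytest.fixture(scope="session")
def packaged_pedigree():
    return eh.load_packaged_pedigree()


@pytest.fixture(scope="session")
def default_panel():
    """A reference panel generated with default parameters, fixed seed."""
    rng = np.random.default_rng(20180125)
    return eh.generate_reference_panel(eh.SeqGenParams(), rng)


@pytest.fixture(scope="session")
def default_marker_panel(default_panel):
    return eh.MarkerPanel.build(
        default_panel.refs_28s_A, default_panel.refs_28s_F, locus="28S"
    )
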