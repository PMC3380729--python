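import numpy as np
import pytest

from pepsl.align import load_substitution_matrix
from pepsl.windows import PeptideWindow, ProteinRecord, WindowCatalog

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_peptide(rng, length):
    return "".join(np.array(list(AA20))[rng.integers(0, 20, length)])


def make_catalog(seqs_by_protein):
    """Build a catalog of full-sequence windows, one per (protein, start)."""
    windows = []
    for pid, seqs in seqs_by_protein.items():
        for start, seq in enumerate(seqs):
            windows.append(PeptideWindow(pid, start * 100, len(seq), seq))
    return WindowCatalog(windows)


@pytest.fixture
def small_mixed_catalog(rng):
    """3 proteins, 6 random windows of length 12."""
    return make_catalog(
        {
            "PA": [random_peptide(rng, 12), random_peptide(rng, 12)],
            "PB": [random_peptide(rng, 12), random_peptide(rng, 12)],
            "PC": [random_peptide(rng, 12), random_peptide(rng, 12)],
        }
    )
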