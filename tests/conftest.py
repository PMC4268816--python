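import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # published_counts / oracles helpers

from codonbias import SyntheticConfig, simulate_cds_set, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def neutral_set():
    """Selection-off, wide-GC3 synthetic set with its ground truth."""
    return simulate_cds_set(SyntheticConfig(n_genes=300, seed=101, selection_strength=0.0))


@pytest.fixture(scope="session")
def selected_set():
    """Moderate-selection synthetic set with its ground truth."""
    return simulate_cds_set(SyntheticConfig(n_genes=300, seed=202, selection_strength=2.0))


@pytest.fixture
def two_record_fasta(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(
        ">geneA some description\n"
        "atggctgctgctgctgct\n"
        ">geneB\n"
        "ATGTTTTTCTTATTG\nTTAA\n"
    )
    return path
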