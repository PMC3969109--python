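import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from hybpipe import synthetic
from hybpipe.align import build_index
from hybpipe.formats import TranscriptDB, TranscriptEntry


@pytest.fixture(scope="session")
def small_db() -> TranscriptDB:
    """20 mRNAs (2 genes with 12 isoforms) + 10 miRNAs, fixed seed."""
    return synthetic.make_transcript_db(
        n_mrna=20, n_mirna=10, mrna_len_range=(300, 600),
        redundancy=12, redundant_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def small_index(small_db):
    return build_index(small_db, word=11)


@pytest.fixture(scope="session")
def plain_db() -> TranscriptDB:
    """Redundancy-free database for recovery-rate assertions."""
    return synthetic.make_transcript_db(
        n_mrna=25, n_mirna=12, mrna_len_range=(300, 600),
        redundancy=1, seed=7)


@pytest.fixture(scope="session")
def plain_index(plain_db):
    return build_index(plain_db, word=11)


@pytest.fixture()
def toy_db() -> TranscriptDB:
    """Hand-written two-transcript database with known sequences."""
    return TranscriptDB([
        TranscriptEntry("MIMAT0000062_hsa-let-7a_microRNA", "hsa-let-7a",
                        "microRNA", "TGAGGTAGTAGGTTGTATAGTT"),
        TranscriptEntry("ENSG0_ENST0_ACTB_mRNA", "ACTB", "mRNA",
                        "ACGT" * 500),
    ])
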