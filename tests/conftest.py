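import numpy as np
import pytest

from baculoscan.genome_io import CircularSequence
from baculoscan.homology import ScoringScheme


@pytest.fixture
def scheme():
    return ScoringScheme()


@pytest.fixture
def toy_sequence():
    return CircularSequence(id="toy", residues="ATGAAATAA", topology="linear")


GENBANK_MINIMAL = """\
LOCUS       TESTSEQ                    9 bp    DNA     linear   VRL 01-JAN-2000
DEFINITION  Minimal test record.
ACCESSION   TESTSEQ
VERSION     TESTSEQ.1
FEATURES             Location/Qualifiers
     CDS             1..9
                     /locus_tag="orfA"
ORIGIN
        1 atgaaataa
//
"""

# 100 bp circular genome; the CDS wraps through the origin via a join.
_WRAP_SEQ = ("ATGGCTGCTGCTGCTTAA" + "C" * 58 + "AAAAAAAAAAAAAAATGGCT")
assert len(_WRAP_SEQ) == 96


def _fold(seq):
    return "\n".join(
        f"{i + 1:>9} " + " ".join(seq[i + k:i + k + 10].lower()
                                  for k in range(0, 60, 10))
        for i in range(0, len(seq), 60))


GENBANK_WRAP = f"""\
LOCUS       WRAPSEQ                   96 bp    DNA     circular VRL 01-JAN-2000
DEFINITION  Circular test record with an origin-spanning CDS.
ACCESSION   WRAPSEQ
VERSION     WRAPSEQ.1
FEATURES             Location/Qualifiers
     CDS             join(92..96,1..13)
                     /locus_tag="wrapped"
ORIGIN
{_fold(_WRAP_SEQ)}
//
"""

WRAP_RESIDUES = _WRAP_SEQ


@pytest.fixture
def genbank_minimal(tmp_path):
    path = tmp_path / "minimal.gb"
    path.write_text(GENBANK_MINIMAL)
    return path


@pytest.fixture
def genbank_wrap(tmp_path):
    path = tmp_path / "wrap.gb"
    path.write_text(GENBANK_WRAP)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
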