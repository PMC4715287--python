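import numpy as np
import pytest

from kspectra import ReadSet, SequenceRecord, readset_from_strings


@pytest.fixture
def fasta_2rec(tmp_path):
    p = tmp_path / "two.fa"
    p.write_text(">r1\nACGTACGT\n>r2\nacgtTTTT\n")
    return p


@pytest.fixture
def fastq_3rec(tmp_path):
    p = tmp_path / "three.fq"
    p.write_text(
        "@a\nACGT\n+\nIIII\n"
        "@b\nTTNA\n+\nII5I\n"
        "@c\nGGGG\n+\n!!!!\n"
    )
    return p


@pytest.fixture
def small_reads():
    return readset_from_strings(["ACGTACGTAA", "TTTTGGGGCC", "ACACACACAC"])


def make_quality_read(name: str, bases: str, quals) -> SequenceRecord:
    if isinstance(quals, int):
        quals = [quals] * len(bases)
    return SequenceRecord(name, bases, tuple(quals))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
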