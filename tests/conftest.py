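import numpy as np
import pytest

from vihmm.seq_io import MappedRead, ReferenceSequence


def make_read(name, pos, cigar, seq, quals=None, contig="ref1"):
    """Convenience constructor with integer-Phred qualities (default Q30)."""
    if quals is None:
        quals = np.full(len(seq), 30.0)
    else:
        quals = np.asarray(quals, dtype=float)
    return MappedRead(name=name, contig=contig, pos=pos, cigar=cigar, seq=seq,
                      quals=quals)


@pytest.fixture
def reference10():
    return ReferenceSequence(name="ref1", bases="ACGTACGTAC")


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)
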