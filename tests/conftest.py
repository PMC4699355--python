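import numpy as np
import pytest

from circlekit.seqio import SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, n: int) -> str:
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def tile_reads(seq: str, read_len: int, step: int, circular: bool,
               prefix: str = "r") -> list[SeqRecord]:
    """Deterministic reads tiling a sequence (wrapping if circular)."""
    src = seq + seq if circular else seq
    reads = []
    i = 0
    pos = 0
    limit = len(seq) if circular else len(seq) - read_len + 1
    while pos < limit:
        reads.append(SeqRecord(f"{prefix}{i}", src[pos:pos + read_len]))
        i += 1
        pos += step
    if not circular and reads and pos - step != len(seq) - read_len:
        reads.append(SeqRecord(f"{prefix}{i}", seq[-read_len:]))
    return reads
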