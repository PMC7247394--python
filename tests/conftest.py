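import numpy as np
import pytest

from chromoscaf.io_formats import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_records(rng):
    """1000 small random sequence records for round-trip properties."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for i in range(1000):
        n = int(rng.integers(1, 200))
        seq = bases[rng.integers(0, 4, n)].tobytes().decode()
        records.append(SequenceRecord(f"rec{i}", seq))
    return records


def make_sequence(rng, n: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, n)].tobytes().decode()
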