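import random

import pytest

from readqa.io import QualityRead


@pytest.fixture
def rng():
    return random.Random(20240915)


@pytest.fixture
def random_reads(rng):
    """Factory for n random equal-length quality reads."""

    def make(n, length, lo=0, hi=40):
        return [
            QualityRead(f"r{i}", tuple(rng.randint(lo, hi) for _ in range(length)))
            for i in range(n)
        ]

    return make


def qual_text(records):
    """Serialize (id, values) pairs in the quality-file dialect."""
    lines = []
    for rid, qvs in records:
        lines.append(f">{rid}")
        lines.append(" ".join(str(q) for q in qvs))
    return "\n".join(lines) + "\n"
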