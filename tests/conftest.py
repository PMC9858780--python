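import numpy as np
import pytest

from divscan.motif_scan import CORE_PATTERN, EXTENDED_PATTERN, compile_pattern
from divscan.seqio import SequenceRecord
from divscan.synth import NATURAL_FREQUENCIES


@pytest.fixture
def core_pattern():
    return compile_pattern(CORE_PATTERN)


@pytest.fixture
def extended_pattern():
    return compile_pattern(EXTENDED_PATTERN)


@pytest.fixture
def random_records():
    """Factory: n random records of a given length at natural frequencies."""

    def make(n: int, length: int = 200, seed: int = 0) -> list[SequenceRecord]:
        rng = np.random.default_rng(seed)
        letters = np.array(list(NATURAL_FREQUENCIES))
        probs = np.array(list(NATURAL_FREQUENCIES.values()))
        probs = probs / probs.sum()
        return [
            SequenceRecord(
                id=f"r{i}", sequence="".join(rng.choice(letters, length, p=probs))
            )
            for i in range(n)
        ]

    return make
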