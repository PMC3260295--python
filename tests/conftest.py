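import numpy as np
import pytest

from isodiv.io_formats import PWM


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def sharp_pwm(motif_id: str, consensus: str, weight: float = 100.0) -> PWM:
    """PWM concentrated on a consensus string (weight vs. 1 elsewhere)."""
    counts = np.ones((4, len(consensus)))
    for j, c in enumerate(consensus):
        counts["ACGT".index(c), j] = weight
    return PWM(motif_id, motif_id, counts)


def random_sequences(rng: np.random.Generator, n: int, length: int, prefix: str = "s"):
    bases = np.array(list("ACGT"))
    return {
        f"{prefix}{i}": "".join(bases[rng.integers(0, 4, size=length)])
        for i in range(n)
    }
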