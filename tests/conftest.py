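import numpy as np
import pytest

from crmscan import PWM, PromoterSet, SequenceRecord, pwm_from_consensus


@pytest.fixture
def toy_pwm():
    """2-position matrix with hand-checkable weights (A=2 / C=1 dominant)."""
    return PWM("toy", np.array([[2.0, 0.0, 0.0, 0.0],
                                [0.0, 1.0, 0.0, 0.0]]))


@pytest.fixture
def sharp_pair():
    """Two informative 10-mers used as the implanted module in simulations."""
    return [pwm_from_consensus("ALPHA", "ACGTGACGTT", dominance=0.92),
            pwm_from_consensus("BETA", "GGATTACCAG", dominance=0.92)]


@pytest.fixture
def small_set():
    return PromoterSet("positive", (
        SequenceRecord("s1", "ACGTACGTACGTACGTACGT"),
        SequenceRecord("s2", "TTTTGGGGCCCCAAAATTTT"),
    ))


def make_random_pwm(rng, name="R", width=4):
    counts = rng.dirichlet(np.full(4, 0.8), size=width) * 100
    w = np.log2(((counts + 0.25) / (counts.sum(1, keepdims=True) + 1)) / 0.25)
    return PWM(name, w)
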