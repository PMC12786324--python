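import numpy as np
import pytest

from circamotif import parse_jaspar, pfm_to_pwm, region_from_sequence


@pytest.fixture
def toy_pfm():
    """2-column PFM: column 0 all-A, column 1 all-C."""
    return parse_jaspar(">M1 toy\nA [4 0]\nC [0 4]\nG [0 0]\nT [0 0]\n")[0]


@pytest.fixture
def toy_pwm(toy_pfm):
    return pfm_to_pwm(toy_pfm)


def consensus_pfm(word: str, count: int = 10):
    """PFM whose only high-count base per column spells the given word."""
    rows = []
    for b in "ACGT":
        vals = " ".join(str(count) if c == b else "0" for c in word)
        rows.append(f"{b} [{vals}]")
    return parse_jaspar(f">CONS {word}\n" + "\n".join(rows) + "\n")[0]


@pytest.fixture
def ebox_pwm():
    """PWM whose consensus (and only max-scoring word) is CACGTG."""
    return pfm_to_pwm(consensus_pfm("CACGTG"))


@pytest.fixture
def region_factory():
    return region_from_sequence


def random_pfm(rng: np.random.Generator, width: int):
    """Random non-degenerate PFM of the given width."""
    from circamotif import PFM, pfm_to_pwm
    from circamotif.errors import DegenerateMatrixError

    while True:
        counts = rng.integers(0, 20, size=(4, width)).astype(float)
        counts[rng.integers(0, 4), :] += 1  # no all-zero column
        pfm = PFM(motif_id="R", name="rand", counts=counts)
        try:
            pfm_to_pwm(pfm)
        except DegenerateMatrixError:
            continue
        return pfm


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = "ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
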