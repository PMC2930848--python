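import numpy as np
import pytest

from cremag.fixtures import FixtureSpec, make_decoy_pwms, make_genome
from cremag.pwm_engine import PFM, pfm_to_pwm


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-gene fixture genome reused by read-only tests."""
    return make_genome(FixtureSpec(seed=11, n_genes=12))


@pytest.fixture(scope="session")
def toy_pwms():
    """Five small decoy matrices (widths <= 12) as (PFM, PWM) pairs."""
    pfms = make_decoy_pwms(5, widths=(4, 6, 8, 10, 12), seed=3)
    return [(p, pfm_to_pwm(p)) for p in pfms]


@pytest.fixture
def onehot_pfm():
    """Width-4 one-hot matrix with consensus ACGT (all-or-nothing scores
    at threshold 100)."""
    counts = np.zeros((4, 4))
    for i, b in enumerate("ACGT"):
        counts["ACGT".index(b), i] = 100
    return PFM(id="TOY0001.1", name="onehot", counts=counts)
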