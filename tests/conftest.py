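import numpy as np
import pytest

from lpamr import fixtures
from lpamr.mr import HarmonizedInstrument, harmonize


@pytest.fixture(scope="session")
def exposure_panel():
    return fixtures.exposure_panel()


@pytest.fixture(scope="session")
def outcome_panel():
    return fixtures.outcome_panel()


@pytest.fixture(scope="session")
def six_instruments(exposure_panel, outcome_panel):
    """The six bundled PCSK9 -> Lp(a) instruments, harmonized."""
    return harmonize(exposure_panel, outcome_panel)


@pytest.fixture
def hand_instruments():
    """Four hand-set instruments with unequal weights for oracle checks."""
    rows = [
        ("s1", 0.30, 0.02, 0.030, 0.010),
        ("s2", 0.20, 0.03, 0.010, 0.008),
        ("s3", -0.25, 0.02, -0.020, 0.012),
        ("s4", 0.40, 0.04, 0.024, 0.015),
    ]
    return [
        HarmonizedInstrument(snp_id=s, beta_exp=be, se_exp=se, beta_out=bo, se_out=so)
        for s, be, se, bo, so in rows
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230928)
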