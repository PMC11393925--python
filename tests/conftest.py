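import numpy as np
import pytest

from channelpat import ChannelPatModel
from channelpat.synthetic import SynthParams

# The published 288-symbol sentence decoded from the 144 selected
# features of the Arabic/Turkish study, kept verbatim as a fixture for
# the symbolic-statistics checks.
PRINTED_SENTENCE = (
    "TFTTPOOPPTFFFFPOFTFFOTTFFFFTFTOOFFFFOOPOFFOTPTFOOFFFFFTFFFFFFFTFPPFFPFTOTPFFFF"
    "TPTFTPPFTFPOFTFFOFOFFFTOFFFFOFTTOPPFFPFFFFFPOPTFFPFFOFFOTOPFFTPFFOFPPFFFPFFPOF"
    "FPFOOPTFFTFFTPOTFPFPTFTOFFPTPTFFFFPFFFPFOTFFFTFFFFTFFOFFPFFFFFOFTFOFFTFFFTFFFF"
    "FOFFFTFPFPFFFFPFOFFPPFFOFOFTPFFFPFFFFFFOTFFPFPFOFTFOFO"
)

PRINTED_SYMBOL_COUNTS = {"F": 158, "T": 44, "P": 45, "O": 41}

PRINTED_TRANSITIONS = {
    "FF": 86, "TT": 3, "PP": 6, "OO": 5,
    "FT": 25, "FP": 24, "FO": 23,
    "TP": 9, "TO": 6, "PO": 7,
    "TF": 26, "PF": 24, "OF": 22,
    "PT": 8, "OT": 7, "OP": 6,
}


@pytest.fixture(scope="session")
def printed_sentence() -> str:
    return PRINTED_SENTENCE


@pytest.fixture(scope="session")
def high_effect_fit():
    """One full pipeline run on strongly separated synthetic data.

    Shared session-wide: several structural and performance checks read
    different aspects of the same fitted result.
    """
    model = ChannelPatModel.from_synthetic(
        SynthParams(effect=1.0, noise_sd=0.2, seed=7)
    )
    return model, model.fit(seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
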