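import numpy as np
import pytest

from linkerlens import synthdata


@pytest.fixture
def ideal_helix20():
    """Cα-only ideal α-helix of 20 ALA residues numbered 300–319."""
    return synthdata.build_helix(20, start_resseq=300)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
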