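import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ssrnn.cells import CellParams, SkipSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small fixed-seed parameter factory for any variant."""

    def make(variant="none", skip=3, input_dim=3, hidden_dim=4, seed=7):
        spec = SkipSpec(variant, skip) if variant != "none" else SkipSpec("none")
        return CellParams.init(input_dim, hidden_dim, spec=spec,
                               rng=np.random.default_rng(seed)), spec

    return make


def zero_out(p):
    """Set every parameter of a CellParams to zero, in place."""
    for t in p.parameters():
        t.value[:] = 0.0
    return p
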