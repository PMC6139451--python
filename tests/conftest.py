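import numpy as np
import pytest

from rfctx.stimulus import (
    ContextWindowSpec,
    StimulusEnsemble,
    apply_basis,
    build_lagged_design,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_ensemble():
    """Small deterministic binary ensemble (5 bars x 30 frames, bright coded)."""
    g = np.random.default_rng(7)
    raw = (g.integers(0, 2, (5, 30)) * 2 - 1).astype(np.int8)
    counts = g.poisson(1.0, 30)
    return StimulusEnsemble(apply_basis(raw, "bright"), counts, 60.0)


@pytest.fixture()
def toy_design(toy_ensemble):
    return build_lagged_design(toy_ensemble, 4)


@pytest.fixture()
def small_window():
    return ContextWindowSpec(height=3, width=3, origin=(1, 1))
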