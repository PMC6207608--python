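import numpy as np
import pytest

from hfld import synthetic


@pytest.fixture(scope="session")
def small_landscape():
    """120x120 landscape shared by read-only tests."""
    spec = synthetic.LandscapeSpec(rows=120, cols=120, seed=7,
                                   protected_fraction=0.2, swamp_fraction=0.05)
    return synthetic.generate_landscape(spec)


@pytest.fixture(scope="session")
def small_history(small_landscape):
    """Moderate-intensity loss history with a gold component."""
    hist = synthetic.HistorySpec(annual_ha=tuple([9.0] * 14), gold_share=0.5)
    return synthetic.generate_history(small_landscape, hist, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
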