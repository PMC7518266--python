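import numpy as np
import pytest

from rtscan.fold_engine import NussinovEngine, get_engine
from rtscan.synth import SynthConfig, make_genome

try:
    import RNA  # noqa: F401

    HAVE_VIENNA = True
except ImportError:  # pragma: no cover
    HAVE_VIENNA = False

vienna_only = pytest.mark.skipif(
    not HAVE_VIENNA, reason="ViennaRNA bindings not importable"
)


@pytest.fixture(scope="session")
def engine():
    """Best available folding engine (vienna where importable)."""
    return get_engine()


@pytest.fixture(scope="session")
def fallback_engine():
    return NussinovEngine()


@pytest.fixture(scope="session")
def small_genome():
    """A 30-gene clean synthetic genome used across parsing/topology tests."""
    cfg = SynthConfig(n_genes=30, intergenic_range=(15, 80), fraction_opposite=0.3)
    return make_genome(cfg, seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987)
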