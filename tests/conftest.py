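import numpy as np
import pytest

from immunotox.config import default_config
from immunotox.engine import initialize_state
from immunotox.tox import ExposureProfile

ALL_LINEAGES = (
    "B", "TH1", "TH2", "TC", "TREG", "NK", "MONO", "MAC", "DC", "MAST", "NEU"
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return default_config()


def make_empty_state(cfg, seed=0, **kwargs):
    """A valid initialized world with zero agents (for targeted tests).

    Homeostatic noise is switched off so lineages with a zero mean stay
    exactly empty.
    """
    cfg = cfg.with_overrides(
        {"lineages": {name: {"sigma": 0.0} for name in ALL_LINEAGES}}
    )
    rng = np.random.default_rng(seed)
    mus = {name: 0.0 for name in ALL_LINEAGES}
    mus.update(kwargs.pop("lineage_mus", {}))
    return initialize_state(
        cfg, rng, lineage_mus=mus, exposure=ExposureProfile.none(), **kwargs
    ), rng


@pytest.fixture
def empty_state(cfg):
    state, rng = make_empty_state(cfg)
    return state, rng
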