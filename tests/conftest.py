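import numpy as np
import pytest

from atriaflow import (impaired_anatomy_config, make_idealized_la,
                       normal_anatomy_config)


@pytest.fixture(scope="session")
def anatomy_2d():
    """Normal planar anatomy: (mesh, la_wf, lv_wf, laa_wf, config)."""
    cfg = normal_anatomy_config(dim=2, seed=1)
    return (*make_idealized_la(cfg), cfg)


@pytest.fixture(scope="session")
def anatomy_2d_impaired():
    cfg = impaired_anatomy_config(dim=2, seed=1)
    return (*make_idealized_la(cfg), cfg)


@pytest.fixture(scope="session")
def anatomy_3d():
    """Normal 3D anatomy with subject-like volume targets."""
    cfg = normal_anatomy_config(dim=3, seed=2)
    return (*make_idealized_la(cfg), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
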