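"""Shared fixtures: one default synthetic world per session, in memory and on disk."""

import pytest

from cancer_orphans import SyntheticConfig, make_world


@pytest.fixture(scope="session")
def world_cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def world(world_cfg):
    """Default three-country synthetic world bundle."""
    return make_world(world_cfg)


@pytest.fixture(scope="session")
def world_dir(world_cfg, tmp_path_factory):
    """The same world written as the five CSV fixtures."""
    out = tmp_path_factory.mktemp("world")
    make_world(world_cfg, out_dir=out)
    return out


@pytest.fixture()
def quiet_world():
    """A deterministic world with no jitter and no child mortality, for
    hand-checkable arithmetic."""
    cfg = SyntheticConfig(seed=0, jitter=0.0, infant_hazard=(0.0, 0.0, 0.0))
    return make_world(cfg)
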