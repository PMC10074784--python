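"""Shared fixtures: small simulated samples and the target that matches them.

The simulated windows are 4 kb stand-ins for the real gene windows: the
detection algorithm is window-size-agnostic, and small windows keep the
suite fast while exercising every stage (region filtering, mate pairing,
clip evidence, consensus, depth).
"""

import pytest

from fusionclip.simulate import SimConfig, simulate_sample
from fusionclip.targets import FusionTargetConfig, GeneRegion

WINDOW_5P = GeneRegion("chr2", 2001, 6000, "+", "EML4")
WINDOW_3P = GeneRegion("chr2", 10001, 14000, "-", "ALK")


def make_target(**overrides) -> FusionTargetConfig:
    kwargs = dict(
        name="EML4-ALK-sim",
        build="synthetic",
        five_prime=WINDOW_5P,
        three_prime=WINDOW_3P,
    )
    kwargs.update(overrides)
    return FusionTargetConfig(**kwargs)


def make_sim_config(**overrides) -> SimConfig:
    kwargs = dict(
        seed=7,
        five_prime_window=WINDOW_5P,
        three_prime_window=WINDOW_3P,
        fusion_fragments=0,
        wildtype_depth=30.0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_target() -> FusionTargetConfig:
    return make_target()


@pytest.fixture(scope="session")
def positive_bundle(tmp_path_factory):
    """A clearly fusion-positive sample: 60 junction-region fragments."""
    cfg = make_sim_config(seed=11, fusion_fragments=60)
    return simulate_sample(cfg, tmp_path_factory.mktemp("sim_pos") / "pos"), cfg


@pytest.fixture(scope="session")
def negative_bundle(tmp_path_factory):
    """A fusion-free sample: background coverage only."""
    cfg = make_sim_config(seed=12)
    return simulate_sample(cfg, tmp_path_factory.mktemp("sim_neg") / "neg"), cfg
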