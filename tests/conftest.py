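"""Shared fixtures: small worlds for unit tests, the demo world for recovery."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from oefish.pipeline import demo_config, run_pipeline
from oefish.sdm_engine import BRTConfig
from oefish.synthetic_data import SyntheticConfig, generate_reaches, generate_surveys, make_truth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A quick world for unit tests: 400 reaches, 4 species."""
    return SyntheticConfig(n_reaches=400, n_sites=350, n_species=4, seed=7)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    reaches = generate_reaches(small_cfg)
    truth = make_truth(reaches, small_cfg)
    surveys = generate_surveys(reaches, truth, small_cfg)
    return small_cfg, reaches, truth, surveys


@pytest.fixture(scope="session")
def fast_brt() -> BRTConfig:
    """A reduced boosting regime for unit tests of the fitting protocol."""
    return BRTConfig(
        min_trees=40,
        max_trees=150,
        initial_learning_rate=0.05,
        n_folds=4,
        bag_fraction=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The full demo pipeline (2,000 reaches, 8 species, seed 42), run once.

    This is the fixture the synthetic-recovery checks exercise; it takes a
    few minutes, so it is session-scoped and shared.
    """
    out = tmp_path_factory.mktemp("demo_run")
    cfg = demo_config(out, seed=42)
    manifest = run_pipeline(cfg)
    reaches = generate_reaches(cfg.synthetic)
    truth = make_truth(reaches, cfg.synthetic)
    return {"cfg": cfg, "manifest": manifest, "out": out, "reaches": reaches, "truth": truth}
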