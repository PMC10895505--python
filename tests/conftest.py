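import dataclasses

import numpy as np
import pytest

from intervmed.schema import default_block_structure
from intervmed.synthetic_data import (
    GeneratorConfig,
    MissingnessConfig,
    MissingnessModel,
    PathCoefficients,
    compute_truth,
    generate_trial,
)


@pytest.fixture(scope="session")
def structure():
    return default_block_structure()


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth of the default generator, shared across tests."""
    return compute_truth(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_trial(default_truth):
    """One complete default trial (n=493, 10 clinics)."""
    ds, truth = generate_trial(GeneratorConfig(seed=42), truth=default_truth)
    return ds, truth


def make_config(**overrides) -> GeneratorConfig:
    """Default generator config with keyword overrides, including nested
    ``paths`` overrides passed as a dict."""
    path_over = overrides.pop("paths", None)
    cfg = GeneratorConfig(**overrides)
    if path_over:
        cfg = dataclasses.replace(cfg, paths=dataclasses.replace(cfg.paths, **path_over))
    return cfg


def no_missing() -> MissingnessConfig:
    return MissingnessConfig(m2=MissingnessModel(0.0), outcome=MissingnessModel(0.0))


def single_mediator_paths(a: float = 2.0, b: float = -0.5, d: float = -1.0) -> dict:
    """Linear-additive scenario where only the activation path is active."""
    return dict(
        m2_arm=a,
        m2_on_m1a=0.0,
        m2_on_m1b=0.0,
        y_m2=b,
        y_arm=d,
        y_m1a=0.0,
        y_m1b=0.0,
        y_m3a=0.0,
        y_m3b=0.0,
    )
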