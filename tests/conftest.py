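"""Shared fixtures: small synthetic scenes built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pyrodelta import SyntheticConfig, generate_scene


@pytest.fixture(scope="session")
def oracle_config() -> SyntheticConfig:
    """Zero-noise, uniform-background scene with all fires in one year.

    Fire sizes are kept moderate so the injected effects stay inside the
    physical bounds of every variable in every season (no clipping), and
    pinning the fire year means no control pixel ever carries a decaying
    effect from another year's burn — the regime in which counterfactual
    recovery is exact.
    """
    return SyntheticConfig(
        grid_nx=90, grid_ny=90, n_fires=8, seed=5,
        lognormal_mu=0.6, lognormal_sigma=0.3,
        years=tuple(range(2002, 2010)), fire_years=(2003,),
    ).zero_noise()


@pytest.fixture(scope="session")
def oracle_scene(oracle_config):
    return generate_scene(oracle_config)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene used by stochastic checks."""
    cfg = SyntheticConfig(grid_nx=100, grid_ny=100, n_fires=25, seed=11,
                          years=tuple(range(2002, 2010)))
    return cfg, *generate_scene(cfg)
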