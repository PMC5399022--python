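"""Shared fixtures: small-grid simulation conditions for fast tests."""

import numpy as np
import pytest

from abtlayers import AlternativeSpec, SimCondition, build_design


@pytest.fixture(scope="session")
def small_cond():
    """Down-scaled simulation grid (24x24x16, radius-2 spheres) preserving
    the statistical structure of the full-size generator."""
    return SimCondition(
        n_scans=50, sigma_noise=3.0, grid=(24, 24, 16), sphere_radius=2.0,
    )


@pytest.fixture(scope="session")
def small_reg(small_cond):
    return build_design(small_cond.design)


@pytest.fixture(scope="session")
def alt_canonical():
    """The canonical alternative: mu_delta1 = 1.5% BOLD, tau = 0.5%."""
    return AlternativeSpec(mu_delta1=1.5, tau=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170421)
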