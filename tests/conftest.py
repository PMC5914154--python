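from dataclasses import replace

import numpy as np
import pytest

import breathpair as bp


@pytest.fixture(scope="session")
def default_cohort():
    """Study-like cohort: 14 subjects x 4 visits, 7 blocks, with missingness."""
    return bp.simulate(bp.default_config(seed=11))


@pytest.fixture(scope="session")
def complete_cohort():
    """Default cohort without any missingness (fully observed)."""
    cfg = replace(bp.default_config(seed=11), missingness={})
    return bp.generate_cohort(cfg)


def single_block_config(
    n_subjects=14,
    n_features=4,
    family="gaussian",
    sigma_s=1.0,
    sigma_e=0.5,
    rho=0.0,
    effects=None,
    seed=0,
    block_name="blk",
):
    """Minimal one-block config for focused generator/classifier tests."""
    spec = bp.BlockSpec(
        name=block_name,
        features=tuple(f"x{i}" for i in range(n_features)),
        family=family,
        baseline=0.0,
        sigma_s=sigma_s,
        sigma_e=sigma_e,
        rho=rho,
    )
    return bp.SyntheticConfig(
        n_subjects=n_subjects,
        blocks=(spec,),
        effects=effects or {},
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
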