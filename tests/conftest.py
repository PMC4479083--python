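import numpy as np
import pandas as pd
import pytest

from serialdex import SimConfig, residualize_batch, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """A reduced cohort (300 genes) with the same planted structure as the default."""
    base = dict(
        n_genes=300,
        prolif_genes=tuple(range(50, 90)),
        immune_genes=tuple(range(90, 120)),
        response_genes=tuple(range(120, 150)),
        hazard_genes=tuple(range(150, 170)),
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """One simulated small cohort plus its batch-residualized matrix."""
    cfg = small_config()
    expr, meta, truth = simulate_cohort(cfg)
    norm = residualize_batch(expr, meta)
    return expr, meta, truth, norm


@pytest.fixture(scope="session")
def quiet_cohort():
    """Low-noise cohort for classifier-recovery checks."""
    cfg = small_config(sigma_noise=0.15, batch_sd=0.1, seed=23)
    expr, meta, truth = simulate_cohort(cfg)
    norm = residualize_batch(expr, meta)
    return expr, meta, truth, norm


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
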