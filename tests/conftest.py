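import numpy as np
import pandas as pd
import pytest

from budnet.synthetic_data import (
    DEFAULT_REGULATORS,
    SimulationConfig,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset shared across read-only tests: two modules,
    organ bias, regulators with targets, batch structure."""
    cfg = SimulationConfig(
        n_genes=260,
        module_sizes=(40, 40),
        trait_profiles=("chilling_up", "chilling_down"),
        bias_fraction=0.25,
        bias_effect=1.5,
        regulators=DEFAULT_REGULATORS,
        n_targets_per_regulator=3,
        batch_effect_sd=0.3,
        noise_dispersion=0.05,
        seed=123,
    )
    matrix, truth = simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def block_expression():
    """Two latent-factor blocks (within-r ~0.9, between-r ~0) plus the
    latent factors, built directly on the log scale."""

    def make(n_per_block=50, n_samples=24, within_r=0.9, seed=0):
        g = np.random.default_rng(seed)
        f1, f2 = g.normal(size=n_samples), g.normal(size=n_samples)
        lam = np.sqrt(within_r)
        noise_sd = np.sqrt(1 - within_r)
        rows, names, labels = [], [], []
        for b, f in ((1, f1), (2, f2)):
            for i in range(n_per_block):
                rows.append(lam * f + noise_sd * g.normal(size=n_samples))
                names.append(f"B{b}_{i:03d}")
                labels.append(f"block{b}")
        expr = pd.DataFrame(rows, index=names, columns=[f"s{j}" for j in range(n_samples)])
        return expr, pd.Series(labels, index=names)

    return make
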