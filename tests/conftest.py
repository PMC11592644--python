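import numpy as np
import pytest

from acepep import (
    GeneratorSpec,
    ModelConfig,
    generate_planted_rule_set,
    load_descriptor_registry,
    split_dataset,
    standard_combinations,
)


@pytest.fixture(scope="session")
def registry():
    return load_descriptor_registry()


@pytest.fixture(scope="session")
def std_combos(registry):
    return standard_combinations(registry)


@pytest.fixture(scope="session")
def planted_small(registry):
    """Small strongly-separable planted-rule dataset with a 7:3 split."""
    ds = generate_planted_rule_set(
        400, registry, set_name="Z-scales", feature_index=0, effect=6.0,
        noise_sd=0.25, seed=7,
    )
    return split_dataset(ds, 0.7, 7)


def tiny_lstm_config(n_features: int, seed: int = 0, **kw) -> ModelConfig:
    """A scaled-down network for fast tests."""
    defaults = dict(
        input_features=n_features,
        hidden_size=24,
        n_lstm_layers=2,
        dropout=(0.2, 0.1),
        max_epochs=40,
        patience=12,
        seed=seed,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
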