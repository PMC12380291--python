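import numpy as np
import pytest

from tabtransfer.interaction import InteractionConfig
from tabtransfer.model import init_model_params
from tabtransfer.schema_data import FeatureSchema, SyntheticSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_schema():
    """Three numerical + three categorical features with vocab sizes 3, 5, 2."""
    return FeatureSchema(
        numerical_names=("age", "nihss_pre", "glucose"),
        categorical_names=("sex", "site", "afib"),
        vocab={
            "sex": ("f", "m", "x"),
            "site": ("a", "b", "c", "d", "e"),
            "afib": ("no", "yes"),
        },
        label_name="label",
    )


@pytest.fixture
def tiny_config():
    return InteractionConfig(d=8, n_heads=2, n_blocks=2, dropout_rate=0.0)


@pytest.fixture
def tiny_model(small_schema, tiny_config):
    return init_model_params(small_schema, tiny_config, seed=7,
                             with_pretrain_heads=True)


@pytest.fixture
def small_dataset():
    spec = SyntheticSpec(
        n_rows=40, n_numerical=3, n_categorical=3, categories_per_feature=3,
        positive_fraction=0.4, signal_strength=1.0, seed=5,
    )
    return generate_synthetic(spec)
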