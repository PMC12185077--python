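import numpy as np
import pandas as pd
import pytest

from fedperiop.datatypes import FeatureSchema
from fedperiop.model import ModelConfig
from fedperiop.preprocessing import DesignMatrices
from fedperiop.synthetic import generate_multisite_cohort, gnv_like
from fedperiop.training import prepare_site


@pytest.fixture(scope="session")
def tiny_schema() -> FeatureSchema:
    return FeatureSchema(
        continuous=("c0", "c1", "c2"),
        binary=("b0", "b1"),
        highcard={"pc": 5, "adm": 3},
        channels=("hr", "sbp"),
    )


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig(
        cont_width=4, bin_width=3, embed_dim=2, hc_width=3,
        fusion_width=4, rnn_hidden=3, attn_dim=3, final_width=4,
    )


def make_batch(schema: FeatureSchema, B: int = 4, T: int = 5, seed: int = 0) -> DesignMatrices:
    """Random model-ready batch conforming to the tiny schema."""
    rng = np.random.default_rng(seed)
    nc, nb = len(schema.continuous), len(schema.binary)
    C = len(schema.channels)
    cards = [schema.highcard[name] for name in sorted(schema.highcard)]
    mask = np.zeros((B, T))
    for i in range(B):
        mask[i, : rng.integers(1, T + 1)] = 1.0
    return DesignMatrices(
        surgery_ids=np.array([f"S{i}" for i in range(B)]),
        x_cont=rng.standard_normal((B, nc)),
        f_cont=(rng.random((B, nc)) > 0.3).astype(float),
        x_bin=(rng.random((B, nb)) > 0.5).astype(float),
        x_high=np.column_stack(
            [rng.integers(0, card + 1, B) for card in cards]
        ),
        y=(rng.random((B, 9)) > 0.7).astype(float),
        attrs=pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], B),
                "race": rng.choice(["white", "african_american"], B),
                "age": rng.integers(20, 90, B),
                "surgery_type": rng.choice(["general", "other"], B),
            }
        ),
        series=rng.standard_normal((B, T, C)),
        series_presence=(rng.random((B, T, C)) > 0.3).astype(float),
        series_mask=mask,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One GNV-like site, 600 surgeries, no intraop — shared across tests."""
    return generate_multisite_cohort([gnv_like(600)], seed=11)[0]


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    designs, split, state = prepare_site(small_cohort, seed=11)
    return designs, split, state
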