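import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietscore.ffq_engine import FoodCompositionTable, FoodItem
from dietscore.scores import load_config
from dietscore.synthetic_cohort import build_composition_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def score_config():
    return load_config()


@pytest.fixture(scope="session")
def synthetic_table() -> FoodCompositionTable:
    return build_composition_table()


@pytest.fixture(scope="session")
def tiny_table() -> FoodCompositionTable:
    """Three-item table small enough for hand/naive-oracle arithmetic."""
    return FoodCompositionTable(
        [
            FoodItem(
                "apple", "Apple", frozenset({"fruit"}), 80.0,
                {"energy_kj": 250.0, "carbohydrate_g": 12.0, "potassium_mg": 110.0},
            ),
            FoodItem(
                "cheese", "Cheese", frozenset({"dairy", "discretionary"}), 40.0,
                {"energy_kj": 1700.0, "fat_g": 34.0, "satfat_g": 22.0,
                 "protein_g": 25.0, "sodium_mg": 650.0},
            ),
            FoodItem(
                "bread", "Wholemeal bread", frozenset({"wholegrain"}), 40.0,
                {"energy_kj": 1000.0, "carbohydrate_g": 40.0, "protein_g": 10.0},
            ),
        ],
        provenance="tiny fixture",
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)
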