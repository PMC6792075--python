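from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import dietshift as ds

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def profiles():
    return ds.load_builtin_profiles()


@pytest.fixture(scope="session")
def profile_table():
    """Independent transposed copy of the published composite table."""
    return pd.read_csv(DATA_DIR / "sandwich_profile_table.csv").set_index("nutrient")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def _simple_item(code=11111111, category=1000, energy=100.0, **kw):
    nv = ds.NutrientVector(energy=energy, **kw)
    return ds.FoodItem(food_code=code, wweia_category=category, amount=100.0, nutrients=nv)


@pytest.fixture()
def simple_item_factory():
    return _simple_item


@pytest.fixture()
def sandwich0_day(profiles):
    """A person-day consisting of exactly one typical-sandwich item."""
    p0 = profiles["Sandwich 0"]
    item = ds.FoodItem(
        food_code=58100000,
        wweia_category=3202,
        amount=250.0,
        nutrients=p0.nutrients,
        groups=p0.groups,
    )
    return ds.PersonDay(
        participant_id="A", stratum="S1", psu="P1", weight=1.0, items=[item]
    )


@pytest.fixture(scope="session")
def small_population():
    cfg = ds.PopulationConfig(n_participants=300, seed=11)
    return cfg, ds.gen_population(cfg)
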