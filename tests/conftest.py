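import pandas as pd
import pytest

from canasta.basket_ingest import (
    BasketRecord,
    PriceTable,
    ResolvedItem,
    default_price_table,
)
from canasta.food_composition import (
    CompositionTable,
    FoodEntry,
    default_composition_table,
)


@pytest.fixture(scope="session")
def table() -> CompositionTable:
    return default_composition_table()


@pytest.fixture(scope="session")
def prices() -> PriceTable:
    return default_price_table()


@pytest.fixture
def english_table() -> CompositionTable:
    """Small hand-built table with English names for resolution tests."""
    entries = {
        "E01": FoodEntry("E01", "canned fish", "meats", 150, 22.0, 7.0, 0.0),
        "E02": FoodEntry("E02", "chicken", "meats", 170, 18.0, 10.0, 0.0),
        "E03": FoodEntry("E03", "rice", "cereals", 358, 7.8, 0.7, 78.8),
        "E04": FoodEntry("E04", "vegetable oil", "oils", 884, 0.0, 100.0, 0.0),
    }
    return CompositionTable(entries)


def make_basket(table: CompositionTable, items_kg: dict[str, float], **kw) -> BasketRecord:
    """BasketRecord from {code: kg} against a composition table."""
    return BasketRecord(
        municipality_id=kw.get("municipality_id", "M1"),
        basket_id=kw.get("basket_id", "B1"),
        beneficiaries=kw.get("beneficiaries", 100),
        items=[
            ResolvedItem(food_code=c, entry=table[c], mass_g=kg * 1000.0)
            for c, kg in items_kg.items()
        ],
    )


def registry_frame(rows: list[dict]) -> pd.DataFrame:
    """Registry DataFrame with sensible defaults for omitted columns."""
    defaults = {
        "municipality_id": "M1",
        "domain": "sierra",
        "budget_group": "A",
        "population": 5000,
        "basket_id": "B1",
        "beneficiaries": 100,
        "food_name": "arroz pilado",
        "quantity": 5.0,
        "unit": "kg",
        "unit_price": float("nan"),
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture
def write_registry_csv(tmp_path):
    def _write(rows: list[dict], name: str = "registry.csv"):
        path = tmp_path / name
        registry_frame(rows).to_csv(path, index=False)
        return path

    return _write
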