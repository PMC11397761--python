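"""Registry ingestion: parsing, unit-to-mass conversion, basket selection and
the inclusion/exclusion flow.

A registry row is one food item of one basket distributed by one municipality.
Municipalities may register several basket variants; the analysis keeps, per
municipality, the variant distributed to the largest number of beneficiaries.
Items registered in "units" (canned fish, typically) carry a unit price and are
converted to mass through mean wholesale/retail market prices.  Baskets enter
the analysis only if they contain at least three distinct foods and no
implausibly extreme quantity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .food_composition import (
    CompositionTable,
    FoodEntry,
    UnresolvedFoodError,
    normalize_name,
    resolve_food,
)

DOMAINS = ("lima_metropolitana", "resto_costa", "sierra", "selva")
BUDGET_GROUPS = ("A", "B", "C", "D")
UNITS = ("kg", "g", "L", "mL", "unit")

#: exact header of a registry CSV
REGISTRY_COLUMNS = [
    "municipality_id",
    "domain",
    "budget_group",
    "population",
    "basket_id",
    "beneficiaries",
    "food_name",
    "quantity",
    "unit",
    "unit_price",
]

# Exchange rate implied by the program's budget-group equivalence
# (50,000 soles <-> US$14,000).
SOLES_PER_USD = 50_000 / 14_000

# Exclusion reason codes
TOO_FEW_FOODS = "too_few_foods"
EXTREME_VALUE = "extreme_value"
UNRESOLVED_ITEMS = "unresolved_items"

DEFAULT_ITEM_CEILING_KG = 100.0
DEFAULT_BASKET_CEILING_KG = 500.0
DEFAULT_UNRESOLVED_FRACTION = 0.20
MIN_DISTINCT_FOODS = 3


def soles_to_usd(soles: float) -> float:
    """Convert soles to US dollars at the program's implied exchange rate."""
    return soles / SOLES_PER_USD


@dataclass(frozen=True)
class Municipality:
    municipality_id: str
    domain: str
    budget_group: str
    population: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.budget_group not in BUDGET_GROUPS:
            raise ValueError(f"unknown budget group {self.budget_group!r}")


@dataclass(frozen=True)
class RawItemRecord:
    municipality_id: str
    basket_id: str
    food_name: str
    quantity: float
    unit: str
    beneficiaries: int
    unit_price: float | None = None

    def __post_init__(self) -> None:
        if not self.quantity > 0:
            raise ValueError(f"quantity must be > 0, got {self.quantity}")
        if self.beneficiaries < 1:
            raise ValueError("beneficiaries must be >= 1")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")


@dataclass(frozen=True)
class ResolvedItem:
    food_code: str
    entry: FoodEntry
    mass_g: float
    weight_approximated: bool = False
    similarity_matched: bool = False


@dataclass
class BasketRecord:
    municipality_id: str
    basket_id: str
    beneficiaries: int
    items: list[ResolvedItem]

    @property
    def n_distinct_foods(self) -> int:
        return len({it.food_code for it in self.items})

    @property
    def total_mass_g(self) -> float:
        return sum(it.mass_g for it in self.items)


@dataclass
class ParsedRegistry:
    records: list[RawItemRecord]
    municipalities: list[Municipality]
    rejects: list[dict] = field(default_factory=list)


class PriceTable:
    """Mean wholesale/retail market price per kg, indexed by normalised name."""

    def __init__(self, frame: pd.DataFrame):
        required = {"food_name", "wholesale_price_per_kg", "retail_price_per_kg"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"price table missing columns: {sorted(missing)}")
        self._mean: dict[str, float] = {}
        for _, row in frame.iterrows():
            key = normalize_name(str(row["food_name"]))
            self._mean[key] = (
                float(row["wholesale_price_per_kg"])
                + float(row["retail_price_per_kg"])
            ) / 2.0

    @classmethod
    def from_csv(cls, path: str | Path) -> "PriceTable":
        return cls(pd.read_csv(path))

    def mean_price_per_kg(self, food_name: str) -> float | None:
        return self._mean.get(normalize_name(food_name))


def default_price_table() -> PriceTable:
    with resources.as_file(
        resources.files("canasta.data").joinpath("price_table.csv")
    ) as p:
        return PriceTable.from_csv(p)


def parse_registry(path: str | Path) -> ParsedRegistry:
    """Parse a registry CSV or JSON file into raw records and municipalities.

    Malformed rows go to ``rejects`` with a reason; they are never silently
    dropped.  An empty file yields an empty registry.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        df = pd.DataFrame(rows, columns=REGISTRY_COLUMNS if not rows else None)
    else:
        try:
            df = pd.read_csv(path, dtype={"municipality_id": str, "basket_id": str})
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=REGISTRY_COLUMNS)
    if df.empty:
        logging.getLogger(__name__).warning("registry %s is empty", path)
        return ParsedRegistry([], [])
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry missing columns: {missing}")

    records: list[RawItemRecord] = []
    rejects: list[dict] = []
    municipalities: dict[str, Municipality] = {}
    for i, row in df.iterrows():
        try:
            muni_id = str(row["municipality_id"])
            if muni_id not in municipalities:
                municipalities[muni_id] = Municipality(
                    municipality_id=muni_id,
                    domain=str(row["domain"]),
                    budget_group=str(row["budget_group"]),
                    population=int(row["population"]),
                )
            price = row["unit_price"]
            price = None if pd.isna(price) else float(price)
            records.append(
                RawItemRecord(
                    municipality_id=muni_id,
                    basket_id=str(row["basket_id"]),
                    food_name=str(row["food_name"]),
                    quantity=float(row["quantity"]),
                    unit=str(row["unit"]),
                    beneficiaries=int(row["beneficiaries"]),
                    unit_price=price,
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"row": int(i), "reason": str(exc)})
    return ParsedRegistry(records, list(municipalities.values()), rejects)


class UnresolvedItemError(ValueError):
    """An item could not be converted to a mass or matched to the table."""


def approximate_weight(
    record: RawItemRecord,
    price_table: PriceTable,
    fallback_name: str | None = None,
) -> float:
    """Mass in grams for a unit-denominated record, via market prices.

    ``mass_g = quantity * (unit_price / mean price per kg) * 1000``: the item's
    registered price buys that many kilograms at the mean of wholesale and
    retail prices.  When the registered spelling has no price entry,
    ``fallback_name`` (typically the similarity-matched food's canonical name)
    is tried before giving up.
    """
    if record.unit != "unit":
        raise ValueError("approximate_weight applies only to unit records")
    if record.unit_price is None or not record.unit_price > 0:
        raise UnresolvedItemError(
            f"unit record {record.food_name!r} has no usable unit_price"
        )
    mean_price = price_table.mean_price_per_kg(record.food_name)
    if mean_price is None and fallback_name is not None:
        mean_price = price_table.mean_price_per_kg(fallback_name)
    if mean_price is None or mean_price <= 0:
        raise UnresolvedItemError(f"no market price for {record.food_name!r}")
    return record.quantity * (record.unit_price / mean_price) * 1000.0


def mass_in_grams(
    record: RawItemRecord,
    price_table: PriceTable,
    density_g_per_ml: float = 1.0,
    fallback_name: str | None = None,
) -> tuple[float, bool]:
    """(mass_g, weight_approximated) for a record in any supported unit.

    Volumes convert at ``density_g_per_ml`` (default 1.0, i.e. 1 mL = 1 g).
    """
    if record.unit == "kg":
        return record.quantity * 1000.0, False
    if record.unit == "g":
        return record.quantity, False
    if record.unit == "L":
        return record.quantity * 1000.0 * density_g_per_ml, False
    if record.unit == "mL":
        return record.quantity * density_g_per_ml, False
    return approximate_weight(record, price_table, fallback_name), True


def select_basket(baskets: dict[str, int]) -> str:
    """The basket distributed to the most beneficiaries; ties break to the
    smallest basket id."""
    if not baskets:
        raise ValueError("municipality has no baskets")
    return min(baskets, key=lambda b: (-baskets[b], b))


def resolve_basket(
    records: list[RawItemRecord],
    table: CompositionTable,
    price_table: PriceTable,
    similarity_floor: float = 0.6,
    densities: dict[str, float] | None = None,
) -> tuple[BasketRecord, list[dict]]:
    """Resolve one basket's raw records to composition-coded items with masses.

    Returns the basket plus per-item rejects (unresolved names or masses).
    ``densities`` optionally maps food group -> g/mL for volume records.
    """
    if not records:
        raise ValueError("empty basket")
    densities = densities or {}
    items: list[ResolvedItem] = []
    item_rejects: list[dict] = []
    for rec in records:
        try:
            code, kind = resolve_food(rec.food_name, table, floor=similarity_floor)
            entry = table[code]
            density = densities.get(entry.group, 1.0)
            mass_g, approximated = mass_in_grams(
                rec, price_table, density, fallback_name=entry.name
            )
            items.append(
                ResolvedItem(
                    food_code=code,
                    entry=entry,
                    mass_g=mass_g,
                    weight_approximated=approximated,
                    similarity_matched=(kind == "similarity"),
                )
            )
        except (UnresolvedFoodError, UnresolvedItemError) as exc:
            item_rejects.append({"food_name": rec.food_name, "reason": str(exc)})
    first = records[0]
    basket = BasketRecord(
        municipality_id=first.municipality_id,
        basket_id=first.basket_id,
        beneficiaries=first.beneficiaries,
        items=items,
    )
    return basket, item_rejects


@dataclass
class Exclusion:
    municipality_id: str
    basket_id: str
    reason: str


def apply_inclusion_exclusion(
    baskets: list[tuple[BasketRecord, list[dict]]],
    item_ceiling_kg: float = DEFAULT_ITEM_CEILING_KG,
    basket_ceiling_kg: float = DEFAULT_BASKET_CEILING_KG,
    max_unresolved_fraction: float = DEFAULT_UNRESOLVED_FRACTION,
) -> tuple[list[BasketRecord], list[Exclusion]]:
    """Partition resolved baskets into kept and excluded-with-reason.

    A basket is excluded when more than ``max_unresolved_fraction`` of its raw
    items failed to resolve, when it has fewer than three distinct foods, or
    when any single item (or the basket total) exceeds the extreme-value
    ceilings.  ``kept`` and ``excluded`` partition the input.
    """
    kept: list[BasketRecord] = []
    excluded: list[Exclusion] = []
    for basket, item_rejects in baskets:
        n_raw = len(basket.items) + len(item_rejects)
        if n_raw and len(item_rejects) / n_raw > max_unresolved_fraction:
            excluded.append(
                Exclusion(basket.municipality_id, basket.basket_id, UNRESOLVED_ITEMS)
            )
            continue
        if basket.n_distinct_foods < MIN_DISTINCT_FOODS:
            excluded.append(
                Exclusion(basket.municipality_id, basket.basket_id, TOO_FEW_FOODS)
            )
            continue
        if (
            any(it.mass_g > item_ceiling_kg * 1000.0 for it in basket.items)
            or basket.total_mass_g > basket_ceiling_kg * 1000.0
        ):
            excluded.append(
                Exclusion(basket.municipality_id, basket.basket_id, EXTREME_VALUE)
            )
            continue
        kept.append(basket)
    return kept, excluded


def ingest_registry(
    registry: ParsedRegistry,
    table: CompositionTable,
    price_table: PriceTable,
    similarity_floor: float = 0.6,
    item_ceiling_kg: float = DEFAULT_ITEM_CEILING_KG,
    basket_ceiling_kg: float = DEFAULT_BASKET_CEILING_KG,
    densities: dict[str, float] | None = None,
) -> tuple[list[BasketRecord], list[Exclusion]]:
    """Full ingest: group records, select one basket per municipality, resolve
    items and apply the inclusion/exclusion flow."""
    by_muni: dict[str, dict[str, list[RawItemRecord]]] = {}
    for rec in registry.records:
        by_muni.setdefault(rec.municipality_id, {}).setdefault(
            rec.basket_id, []
        ).append(rec)

    resolved: list[tuple[BasketRecord, list[dict]]] = []
    for muni_id in sorted(by_muni):
        baskets = by_muni[muni_id]
        chosen = select_basket(
            {bid: recs[0].beneficiaries for bid, recs in baskets.items()}
        )
        resolved.append(
            resolve_basket(
                baskets[chosen], table, price_table, similarity_floor, densities
            )
        )
    return apply_inclusion_exclusion(resolved, item_ceiling_kg, basket_ceiling_kg)
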