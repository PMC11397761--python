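"""Food-composition reference table: loading, lookup and name resolution.

The table plays the role the Peruvian food-composition tables (TPCA) play in
basket surveillance work: per-100 g energy and macronutrients plus a food-group
assignment from the ten groups of the national food guide.  Registry food names
are free text, so resolution first tries an exact match on a normalised name
and falls back to the closest entry by a token-set string similarity — the
"similar food" approximation used when a product (canned tuna, say) has no code
of its own.

The packaged fixture table (``data/composition_table.csv``) is a synthetic
stand-in transcribed from public food-composition references; it spans all ten
groups with 40 common basket foods.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

FOOD_GROUPS = (
    "sugars",
    "meats",
    "cereals",
    "oils",
    "dairy",
    "legumes",
    "fruits",
    "eggs",
    "vegetables",
    "tubers",
)

#: exact header required of a composition-table CSV
COMPOSITION_COLUMNS = [
    "code",
    "name",
    "group",
    "energy_kcal_100g",
    "protein_g_100g",
    "fat_g_100g",
    "carb_g_100g",
]

DEFAULT_SIMILARITY_FLOOR = 0.6


class CompositionError(ValueError):
    """Schema or validation failure in a composition table."""


class UnresolvedFoodError(LookupError):
    """No table entry matches the food name above the similarity floor."""

    def __init__(self, name: str, floor: float):
        self.name = name
        self.floor = floor
        super().__init__(f"no composition entry for {name!r} at similarity >= {floor}")


@dataclass(frozen=True)
class FoodEntry:
    """One food of the composition table, per 100 g edible portion."""

    code: str
    name: str
    group: str
    energy_kcal_100g: float
    protein_g_100g: float
    fat_g_100g: float
    carb_g_100g: float

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise CompositionError(
                f"entry {self.code}: unknown food group {self.group!r}"
            )
        for attr in ("energy_kcal_100g", "protein_g_100g", "fat_g_100g", "carb_g_100g"):
            if getattr(self, attr) < 0:
                raise CompositionError(
                    f"entry {self.code}: negative {attr} ({getattr(self, attr)})"
                )
        macro_sum = self.protein_g_100g + self.fat_g_100g + self.carb_g_100g
        if macro_sum > 100 + 1e-9:
            raise CompositionError(
                f"entry {self.code}: macronutrients sum to {macro_sum} g per 100 g"
            )


def normalize_name(name: str) -> str:
    """Lowercase, strip accents and punctuation, collapse whitespace."""
    text = unicodedata.normalize("NFKD", name)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = text.lower()
    text = re.sub(r"[^a-z0-9\s]", " ", text)
    return re.sub(r"\s+", " ", text).strip()


def token_set_similarity(a: str, b: str) -> float:
    """Similarity in [0, 1] between two normalised names.

    Token-set construction: compare the shared-token string against each
    side's full sorted-token string and the full strings against each other,
    taking the best ratio.  A name that is a token-subset of another ("canned
    fish" vs "canned tuna in oil") scores on its shared part, which is the
    behaviour the similar-food fallback needs.
    """
    ta, tb = set(a.split()), set(b.split())
    if not ta or not tb:
        return 0.0
    inter = " ".join(sorted(ta & tb))
    sa = " ".join(sorted(ta))
    sb = " ".join(sorted(tb))
    candidates = [(sa, sb)]
    if inter:
        candidates += [(inter, sa), (inter, sb)]
    return max(SequenceMatcher(None, x, y).ratio() for x, y in candidates)


@dataclass
class CompositionTable:
    """Composition entries keyed by code, with a normalised-name index."""

    entries: dict[str, FoodEntry]
    _name_index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise CompositionError("composition table is empty")
        self._name_index = {}
        for code in sorted(self.entries):
            key = normalize_name(self.entries[code].name)
            # first (lexicographically smallest) code wins on duplicate names
            self._name_index.setdefault(key, code)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> FoodEntry:
        return self.entries[code]

    def __iter__(self) -> Iterable[FoodEntry]:
        return iter(self.entries.values())

    def codes_in_group(self, group: str) -> list[str]:
        return sorted(c for c, e in self.entries.items() if e.group == group)


def load_composition_table(path: str | Path) -> CompositionTable:
    """Read a composition-table CSV and validate every row.

    Raises :class:`CompositionError` naming the offending column, row or code
    on a malformed file.
    """
    df = pd.read_csv(path, dtype={"code": str})
    missing = [c for c in COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise CompositionError(f"composition table missing columns: {missing}")
    entries: dict[str, FoodEntry] = {}
    for i, row in df.iterrows():
        try:
            entry = FoodEntry(
                code=str(row["code"]),
                name=str(row["name"]),
                group=str(row["group"]),
                energy_kcal_100g=float(row["energy_kcal_100g"]),
                protein_g_100g=float(row["protein_g_100g"]),
                fat_g_100g=float(row["fat_g_100g"]),
                carb_g_100g=float(row["carb_g_100g"]),
            )
        except CompositionError as exc:
            raise CompositionError(f"row {i}: {exc}") from exc
        if entry.code in entries:
            raise CompositionError(f"duplicate code {entry.code!r}")
        entries[entry.code] = entry
    return CompositionTable(entries)


def default_composition_table() -> CompositionTable:
    """The packaged 40-food fixture table."""
    with resources.as_file(
        resources.files("canasta.data").joinpath("composition_table.csv")
    ) as p:
        return load_composition_table(p)


def resolve_food(
    name: str,
    table: CompositionTable,
    group_hint: str | None = None,
    floor: float = DEFAULT_SIMILARITY_FLOOR,
) -> tuple[str, str]:
    """Resolve a free-text food name to a table code.

    Returns ``(code, match_kind)`` with ``match_kind`` either ``"exact"``
    (normalised names equal) or ``"similarity"`` (closest entry above
    ``floor``, restricted to ``group_hint`` when given).  Ties break to the
    lexicographically smallest code, so resolution is deterministic.
    """
    key = normalize_name(name)
    if not key:
        raise ValueError("empty food name after normalization")
    exact = table._name_index.get(key)
    if exact is not None:
        return exact, "exact"
    best_score, best_code = 0.0, None
    for code in sorted(table.entries):
        entry = table.entries[code]
        if group_hint is not None and entry.group != group_hint:
            continue
        score = token_set_similarity(key, normalize_name(entry.name))
        if score > best_score + 1e-12:
            best_score, best_code = score, code
    if best_code is None or best_score < floor:
        raise UnresolvedFoodError(name, floor)
    return best_code, "similarity"


def nutrients_for_mass(
    entry: FoodEntry, mass_g: float
) -> tuple[float, float, float, float]:
    """Macronutrient grams and table energy for ``mass_g`` grams of a food.

    Linear per-100 g scaling; returns
    ``(protein_g, fat_g, carb_g, table_energy_kcal)``.
    """
    if not mass_g >= 0:
        raise ValueError(f"mass must be >= 0, got {mass_g}")
    f = mass_g / 100.0
    return (
        entry.protein_g_100g * f,
        entry.fat_g_100g * f,
        entry.carb_g_100g * f,
        entry.energy_kcal_100g * f,
    )
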