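"""Per-basket energy and macronutrient accounting.

Energy available from a basket is computed with the Atwater general factors —
4 kcal/g for protein and carbohydrate, 9 kcal/g for fat — and the caloric
distribution is each macronutrient's energy as a percentage of that total.
Using the Atwater sum (rather than the composition table's energy column) as
the denominator makes the three percentages sum to exactly 100; the
table-energy total is still carried along for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

from .basket_ingest import BasketRecord
from .food_composition import FOOD_GROUPS, nutrients_for_mass

ATWATER = {"protein": 4.0, "fat": 9.0, "carb": 4.0}

MACRONUTRIENTS = ("protein", "fat", "carb")


class UndefinedDistributionError(ValueError):
    """Basket has zero Atwater energy; caloric distribution is undefined."""


@dataclass(frozen=True)
class NutrientProfile:
    """Basket totals: grams per macronutrient, energy, and caloric distribution."""

    protein_g: float
    fat_g: float
    carb_g: float
    energy_kcal: float
    table_energy_kcal: float
    pct_protein: float
    pct_fat: float
    pct_carb: float

    def pct(self, macro: str) -> float:
        return getattr(self, f"pct_{macro}")


def atwater_energy(protein_g: float, fat_g: float, carb_g: float) -> float:
    return (
        ATWATER["protein"] * protein_g
        + ATWATER["fat"] * fat_g
        + ATWATER["carb"] * carb_g
    )


def basket_profile(basket: BasketRecord) -> NutrientProfile:
    """Sum item contributions into a basket-level nutrient profile.

    Every resolved item contributes; raises
    :class:`UndefinedDistributionError` when total Atwater energy is zero so
    the basket can be flagged rather than silently zeroed.
    """
    protein = fat = carb = table_energy = 0.0
    for item in basket.items:
        p, f, c, e = nutrients_for_mass(item.entry, item.mass_g)
        protein += p
        fat += f
        carb += c
        table_energy += e
    energy = atwater_energy(protein, fat, carb)
    if energy <= 0:
        raise UndefinedDistributionError(
            f"basket {basket.basket_id} of {basket.municipality_id} "
            "has zero energy"
        )
    return NutrientProfile(
        protein_g=protein,
        fat_g=fat,
        carb_g=carb,
        energy_kcal=energy,
        table_energy_kcal=table_energy,
        pct_protein=ATWATER["protein"] * protein / energy * 100.0,
        pct_fat=ATWATER["fat"] * fat / energy * 100.0,
        pct_carb=ATWATER["carb"] * carb / energy * 100.0,
    )


def group_quantities(basket: BasketRecord) -> dict[str, float]:
    """Total kilograms per food group; groups absent from the basket are 0.

    Volumes were already converted to mass at ingest, so oils report the
    numeric litre quantity when density 1 g/mL is in effect.
    """
    totals = {g: 0.0 for g in FOOD_GROUPS}
    for item in basket.items:
        totals[item.entry.group] += item.mass_g / 1000.0
    return totals
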