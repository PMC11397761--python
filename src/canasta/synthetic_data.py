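"""Synthetic basket-registry generator.

Emulates the structure of a municipal emergency food-basket registry: a frame
of municipalities stratified by geographic domain and budget group, one to
three basket variants per municipality (53 % register more than one), and one
row per food item with quantity, unit and optional unit price.  Data-entry
pathologies of the real registries are injected at configurable rates with
truth labels, so the ingest flow can be tested end to end:

* ``unit``-denominated items (weight unreported, price present), concentrated
  in the meats group as with canned fish in practice;
* extreme quantities (hundreds of kilograms in a single item);
* variant spellings of canned-fish products that only resolve by the
  similar-food approximation.

Per-group quantities are log-normal — positive and right-skewed, matching the
asymmetric IQRs of observed baskets — parameterised by a target median and
quartile ratio.  Domain and budget effects are multiplicative shifts whose
product over the strata of each factor is 1, so national medians sit at the
configured targets.  The caloric-distribution medians the configuration
implies are defined by a deterministic large-n simulation of the same
generative model (:func:`caloric_distribution_targets`), independent of the
CSV/ingest path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basket_ingest import BUDGET_GROUPS, DOMAINS, REGISTRY_COLUMNS, Municipality, PriceTable
from .food_composition import CompositionTable
from .nutrient_accounting import atwater_energy

CORE_GROUPS = ("sugars", "meats", "cereals", "oils", "dairy", "legumes")
OPTIONAL_GROUPS = ("fruits", "eggs", "vegetables", "tubers")

#: z(0.75) - z(0.25); converts a quartile ratio to a log-normal sigma
_IQR_Z_SPAN = 1.3489795003921634

#: variant canned-fish spellings that lack their own entry and must resolve
#: by similarity to a packaged meats food
MEAT_ALIASES = {
    "conserva de atun en aceite": "conserva de pescado en aceite",
    "conserva de atun en agua": "conserva de pescado en agua",
    "filete de anchoveta en conserva": "anchoveta en conserva",
}


def lognormal_sigma(q1: float, q3: float) -> float:
    """Sigma of a log-normal with quartiles in ratio q3/q1."""
    if not 0 < q1 <= q3:
        raise ValueError("need 0 < q1 <= q3")
    if q1 == q3:
        return 0.0
    return math.log(q3 / q1) / _IQR_Z_SPAN


@dataclass
class GeneratorConfig:
    """Conditions of the emulated registry.

    Quantity targets are national medians with quartiles, in kg (oils are
    registered in litres; 1 L is carried as 1 kg under the default density).
    Error rates: ``p_unit_records`` is the overall fraction of items emitted
    in "units", with ``unit_meat_share`` of them drawn from meats;
    ``p_extreme`` is the fraction of baskets given one implausible quantity;
    ``p_multi_basket`` the fraction of municipalities with more than one
    basket variant; ``p_alias`` the chance a meats item uses a variant
    spelling resolvable only by similarity.
    """

    n_municipalities: int = 1874
    domain_weights: dict[str, float] = field(
        default_factory=lambda: {d: 0.25 for d in DOMAINS}
    )
    budget_weights: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in BUDGET_GROUPS}
    )
    group_targets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "sugars": (5.0, 3.0, 6.0),
            "meats": (0.7, 0.5, 1.0),
            "cereals": (13.1, 10.0, 17.0),
            "oils": (2.0, 1.0, 3.0),
            "dairy": (1.6, 1.2, 2.0),
            "legumes": (2.0, 2.0, 4.0),
        }
    )
    # multiplicative shifts; product over the levels of each factor is 1 per
    # group, so the national mixture median stays at the configured target
    domain_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "meats": {
                "lima_metropolitana": 1.5,
                "resto_costa": 0.8,
                "sierra": 1.0,
                "selva": 1.0 / 1.2,
            },
            "sugars": {
                "lima_metropolitana": 0.64,
                "resto_costa": 1.0,
                "sierra": 1.25,
                "selva": 1.25,
            },
            "cereals": {
                "lima_metropolitana": 0.8,
                "resto_costa": 1.0,
                "sierra": 1.0,
                "selva": 1.25,
            },
            "oils": {
                "lima_metropolitana": 0.8,
                "resto_costa": 0.8,
                "sierra": 1.25,
                "selva": 1.25,
            },
            "legumes": {
                "lima_metropolitana": 0.8,
                "resto_costa": 1.0,
                "sierra": 1.25,
                "selva": 1.0,
            },
        }
    )
    budget_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "meats": {"A": 0.8, "B": 1.0, "C": 1.0, "D": 1.25},
            "cereals": {"A": 1.25, "B": 1.0, "C": 1.0, "D": 0.8},
            "sugars": {"A": 1.25, "B": 1.0, "C": 1.0, "D": 0.8},
            "oils": {"A": 1.25, "B": 1.0, "C": 1.0, "D": 0.8},
            "dairy": {"A": 1.25, "B": 1.0, "C": 1.0, "D": 0.8},
            "legumes": {"A": 1.25, "B": 1.0, "C": 1.0, "D": 0.8},
        }
    )
    p_split: float = 0.35  # chance a core group is spread over two foods
    optional_group_p: float = 0.15
    optional_median_kg: float = 1.0
    optional_sigma: float = 0.4
    p_unit_records: float = 0.10
    unit_meat_share: float = 0.522
    p_extreme: float = 0.02
    p_multi_basket: float = 0.53
    p_alias: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs, levels in (
            ("domain_weights", self.domain_weights, DOMAINS),
            ("budget_weights", self.budget_weights, BUDGET_GROUPS),
        ):
            if set(probs) != set(levels):
                raise ValueError(f"{name} must cover exactly {levels}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for p in (
            self.p_split,
            self.optional_group_p,
            self.p_unit_records,
            self.p_extreme,
            self.p_multi_basket,
            self.p_alias,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def sigma(self, group: str) -> float:
        _, q1, q3 = self.group_targets[group]
        return lognormal_sigma(q1, q3)


def generate_frame(config: GeneratorConfig, seed: int | None = None) -> list[Municipality]:
    """Draw the municipality frame: strata per the configured weights and a
    log-normal population size.  Deterministic under the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_municipalities
    if n == 0:
        return []
    domains = rng.choice(
        DOMAINS, size=n, p=[config.domain_weights[d] for d in DOMAINS]
    )
    budgets = rng.choice(
        BUDGET_GROUPS, size=n, p=[config.budget_weights[b] for b in BUDGET_GROUPS]
    )
    populations = np.maximum(
        500, np.rint(np.exp(np.log(8000) + 1.0 * rng.standard_normal(n)))
    ).astype(int)
    width = len(str(n))
    return [
        Municipality(
            municipality_id=f"M{i+1:0{width}d}",
            domain=str(domains[i]),
            budget_group=str(budgets[i]),
            population=int(populations[i]),
        )
        for i in range(n)
    ]


def _group_food_arrays(table: CompositionTable):
    """Per-group code lists and per-gram macro coefficient arrays."""
    codes: dict[str, list[str]] = {}
    macros: dict[str, np.ndarray] = {}
    for g in CORE_GROUPS + OPTIONAL_GROUPS:
        cs = table.codes_in_group(g)
        if not cs:
            raise ValueError(f"composition table has no foods in group {g!r}")
        codes[g] = cs
        macros[g] = np.array(
            [
                [
                    table[c].protein_g_100g,
                    table[c].fat_g_100g,
                    table[c].carb_g_100g,
                ]
                for c in cs
            ]
        )
    return codes, macros


def _sample_baskets(
    config: GeneratorConfig,
    table: CompositionTable,
    domain_idx: np.ndarray,
    budget_idx: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Vectorised draw of basket compositions for given stratum indices.

    Shared by registry emission and by the implied-target computation so both
    follow the identical generative model.
    """
    n = domain_idx.size
    codes, _ = _group_food_arrays(table)
    sample: dict = {"n": n, "codes": codes, "groups": {}}
    for g in CORE_GROUPS:
        median, _, _ = config.group_targets[g]
        dom_eff = np.array(
            [config.domain_effects.get(g, {}).get(d, 1.0) for d in DOMAINS]
        )[domain_idx]
        bud_eff = np.array(
            [config.budget_effects.get(g, {}).get(b, 1.0) for b in BUDGET_GROUPS]
        )[budget_idx]
        q = median * dom_eff * bud_eff * np.exp(
            config.sigma(g) * rng.standard_normal(n)
        )
        k = len(codes[g])
        food1 = rng.integers(0, k, size=n)
        food2 = rng.integers(0, k, size=n)
        split = rng.random(n) < config.p_split
        frac = np.where(split, rng.uniform(0.3, 0.7, size=n), 1.0)
        sample["groups"][g] = {
            "q_kg": q,
            "food1": food1,
            "food2": food2,
            "split": split,
            "frac": frac,
        }
    for g in OPTIONAL_GROUPS:
        include = rng.random(n) < config.optional_group_p
        q = config.optional_median_kg * np.exp(
            config.optional_sigma * rng.standard_normal(n)
        )
        food = rng.integers(0, len(codes[g]), size=n)
        sample["groups"][g] = {"q_kg": q, "food1": food, "include": include}
    return sample


def _sample_macros(sample: dict, table: CompositionTable) -> np.ndarray:
    """(n, 3) array of protein/fat/carb grams per sampled basket."""
    _, macros = _group_food_arrays(table)
    n = sample["n"]
    totals = np.zeros((n, 3))
    for g in CORE_GROUPS:
        grp = sample["groups"][g]
        m1 = macros[g][grp["food1"]]
        m2 = macros[g][grp["food2"]]
        frac = grp["frac"][:, None]
        # kg -> g of food, composition per 100 g -> factor 10
        totals += grp["q_kg"][:, None] * 10.0 * (frac * m1 + (1 - frac) * m2)
    for g in OPTIONAL_GROUPS:
        grp = sample["groups"][g]
        m = macros[g][grp["food1"]]
        totals += (
            grp["include"][:, None] * grp["q_kg"][:, None] * 10.0 * m
        )
    return totals


def caloric_distribution_targets(
    config: GeneratorConfig,
    table: CompositionTable,
    n: int = 50_000,
    seed: int = 1_234_567,
) -> dict[str, float]:
    """Median caloric-distribution percentages implied by the configuration.

    Defined by a large-n direct simulation of the generative model (fixed
    internal seed by default), bypassing CSV serialisation and ingest; the
    pipeline's recovered medians should approach these as the registry grows.
    """
    rng = np.random.default_rng(seed)
    domain_idx = rng.choice(
        len(DOMAINS), size=n, p=[config.domain_weights[d] for d in DOMAINS]
    )
    budget_idx = rng.choice(
        len(BUDGET_GROUPS), size=n, p=[config.budget_weights[b] for b in BUDGET_GROUPS]
    )
    sample = _sample_baskets(config, table, domain_idx, budget_idx, rng)
    macros = _sample_macros(sample, table)
    energy = atwater_energy(macros[:, 0], macros[:, 1], macros[:, 2])
    return {
        "pct_protein": float(np.median(4.0 * macros[:, 0] / energy * 100.0)),
        "pct_fat": float(np.median(9.0 * macros[:, 1] / energy * 100.0)),
        "pct_carb": float(np.median(4.0 * macros[:, 2] / energy * 100.0)),
    }


def generate_registry(
    frame: list[Municipality],
    config: GeneratorConfig,
    table: CompositionTable,
    price_table: PriceTable,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Emit registry rows for a municipality frame, plus truth labels.

    Returns ``(rows, truth)`` where ``rows`` follows the registry CSV schema
    and ``truth`` records every injected unit record, extreme quantity and
    alias spelling, so downstream detection can be checked against ground
    truth.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    if not frame:
        return pd.DataFrame(columns=REGISTRY_COLUMNS), {
            "unit_items": [],
            "extreme_baskets": [],
            "alias_items": [],
        }

    # basket variants per municipality
    multi = rng.random(len(frame)) < config.p_multi_basket
    n_variants = np.where(multi, rng.integers(2, 4, size=len(frame)), 1)
    domain_code = {d: i for i, d in enumerate(DOMAINS)}
    budget_code = {b: i for i, b in enumerate(BUDGET_GROUPS)}
    domain_idx = np.repeat([domain_code[m.domain] for m in frame], n_variants)
    budget_idx = np.repeat([budget_code[m.budget_group] for m in frame], n_variants)
    muni_of_basket = np.repeat(np.arange(len(frame)), n_variants)
    variant_index = np.concatenate([np.arange(k) for k in n_variants])

    sample = _sample_baskets(config, table, domain_idx, budget_idx, rng)
    codes = sample["codes"]
    n_baskets = sample["n"]
    beneficiaries = np.maximum(
        1,
        np.rint(
            np.array([frame[i].population for i in muni_of_basket])
            * rng.uniform(0.05, 0.30, size=n_baskets)
        ),
    ).astype(int)

    # assemble per-basket item lists: (food_name, group, quantity_kg)
    rows: list[dict] = []
    truth = {"unit_items": [], "extreme_baskets": [], "alias_items": []}
    alias_names = sorted(MEAT_ALIASES)
    name_of = {c: table[c].name for g in codes for c in codes[g]}

    for b in range(n_baskets):
        muni = frame[muni_of_basket[b]]
        basket_id = f"{muni.municipality_id}-B{1 + int(variant_index[b])}"
        items: list[tuple[str, str, float]] = []
        for g in CORE_GROUPS:
            grp = sample["groups"][g]
            q = float(grp["q_kg"][b])
            c1 = codes[g][grp["food1"][b]]
            if grp["split"][b]:
                c2 = codes[g][grp["food2"][b]]
                f = float(grp["frac"][b])
                if c1 == c2:
                    items.append((name_of[c1], g, q))
                else:
                    items.append((name_of[c1], g, q * f))
                    items.append((name_of[c2], g, q * (1 - f)))
            else:
                items.append((name_of[c1], g, q))
        for g in OPTIONAL_GROUPS:
            grp = sample["groups"][g]
            if grp["include"][b]:
                items.append((name_of[codes[g][grp["food1"][b]]], g, float(grp["q_kg"][b])))

        # alias spellings for meats
        renamed = []
        for name, g, q in items:
            if g == "meats" and rng.random() < config.p_alias:
                alias = alias_names[int(rng.integers(0, len(alias_names)))]
                truth["alias_items"].append(
                    {"municipality_id": muni.municipality_id, "basket_id": basket_id,
                     "food_name": alias}
                )
                renamed.append((alias, g, q))
            else:
                renamed.append((name, g, q))
        items = renamed

        # one extreme quantity per affected basket
        if rng.random() < config.p_extreme and items:
            j = int(rng.integers(0, len(items)))
            name, g, _ = items[j]
            items[j] = (name, g, float(rng.uniform(150.0, 1000.0)))
            truth["extreme_baskets"].append(
                {"municipality_id": muni.municipality_id, "basket_id": basket_id}
            )

        # choose which items become "unit" records, meats-weighted so the
        # configured overall rate and meats share both hold in expectation
        n_items = len(items)
        k_units = rng.binomial(n_items, config.p_unit_records)
        unit_slots: set[int] = set()
        if k_units > 0:
            is_meat = np.array([g == "meats" for _, g, _ in items])
            n_meat = int(is_meat.sum())
            n_other = n_items - n_meat
            if 0 < n_meat < n_items:
                s = config.unit_meat_share
                w_meat = (s / (1 - s)) * (n_other / n_meat)
                weights = np.where(is_meat, w_meat, 1.0)
            else:
                weights = np.ones(n_items)
            weights = weights / weights.sum()
            unit_slots = set(
                rng.choice(n_items, size=min(k_units, n_items), replace=False, p=weights)
            )

        for j, (name, g, q_kg) in enumerate(items):
            unit = "L" if g == "oils" else "kg"
            quantity = q_kg
            unit_price = np.nan
            if j in unit_slots:
                base = MEAT_ALIASES.get(name, name)
                mean_price = price_table.mean_price_per_kg(base)
                if mean_price is not None:
                    n_units = int(rng.integers(1, 25))
                    unit = "unit"
                    quantity = float(n_units)
                    unit_price = round(q_kg * mean_price / n_units, 2)
                    if unit_price <= 0:
                        unit_price = 0.01
                    truth["unit_items"].append(
                        {"municipality_id": muni.municipality_id,
                         "basket_id": basket_id, "food_name": name,
                         "true_mass_kg": q_kg}
                    )
            rows.append(
                {
                    "municipality_id": muni.municipality_id,
                    "domain": muni.domain,
                    "budget_group": muni.budget_group,
                    "population": muni.population,
                    "basket_id": basket_id,
                    "beneficiaries": int(beneficiaries[b]),
                    "food_name": name,
                    "quantity": round(quantity, 4),
                    "unit": unit,
                    "unit_price": unit_price,
                }
            )
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS), truth


def write_registry(
    rows: pd.DataFrame, path: str | Path, truth: dict | None = None
) -> None:
    """Write registry rows as CSV (and truth labels as a JSON sidecar)."""
    rows.to_csv(path, index=False, float_format="%.4f")
    if truth is not None:
        sidecar = Path(path).with_suffix(".truth.json")
        with open(sidecar, "w") as fh:
            json.dump(truth, fh, indent=1)
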