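"""End-to-end pipeline: ingest -> nutrient accounting -> AMDR classification
-> stratified summaries, with report tables and a run manifest.

Outputs (plain CSV + JSON under ``out_dir``):

* ``profiles.csv`` — one row per analysed municipality: energy, macronutrient
  grams and caloric-distribution percentages;
* ``group_quantities.csv`` — kilograms per food group and basket;
* ``distribution_summary.csv`` — median (IQR) of the caloric distribution by
  geographic domain and budget group, with Kruskal–Wallis tests and compact
  letters;
* ``group_quantity_summary.csv`` — the same layout for kg per food group;
* ``adequacy_summary.csv`` — deficit/excess proportions per macronutrient and
  overall adequacy, by stratum and standard;
* ``flow.json`` / ``manifest.json`` — the inclusion/exclusion flow and run
  metadata; the manifest asserts flow conservation (municipalities in =
  analysed + excluded, by reason).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .amdr_classification import (
    adequacy_summary,
    classification_frame,
    default_standards,
    load_standards,
)
from .basket_ingest import (
    default_price_table,
    ingest_registry,
    parse_registry,
    PriceTable,
)
from .food_composition import default_composition_table, load_composition_table
from .nutrient_accounting import (
    UndefinedDistributionError,
    basket_profile,
    group_quantities,
)
from .stratified_stats import median_iqr, posthoc_letters
from .synthetic_data import CORE_GROUPS


@dataclass
class PipelineConfig:
    registry_path: str
    out_dir: str
    composition_path: str | None = None
    price_path: str | None = None
    standards_path: str | None = None
    similarity_floor: float = 0.6
    item_ceiling_kg: float = 100.0
    basket_ceiling_kg: float = 500.0
    expansion_weights: dict[str, float] | None = None
    alpha: float = 0.05
    seed: int = 0
    densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    profiles: pd.DataFrame
    group_kg: pd.DataFrame
    adequacy: pd.DataFrame
    distribution_summary: pd.DataFrame
    group_quantity_summary: pd.DataFrame
    flow: dict
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    # out_dir is excluded: reruns into different directories are the same run
    payload = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stratified_summary(
    df: pd.DataFrame, variables: list[str], alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/IQR + compact letters per stratum, for domain and budget factors."""
    summary_rows, test_rows = [], []
    for factor in ("domain", "budget_group"):
        for var in variables:
            groups = {
                str(level): sub[var].to_numpy()
                for level, sub in df.groupby(factor)
                if len(sub) > 0
            }
            med, q1, q3 = median_iqr(df[var])
            if len(groups) >= 2 and sum(len(v) for v in groups.values()) >= 3:
                cmp = posthoc_letters(groups, alpha=alpha)
                letters = cmp.letters
                test_rows.append(
                    {
                        "variable": var,
                        "factor": factor,
                        "H": cmp.h,
                        "df": len(groups) - 1,
                        "p": cmp.p,
                    }
                )
            else:
                letters = {g: "a" for g in groups}
            for level in sorted(groups):
                m, lo, hi = median_iqr(groups[level])
                summary_rows.append(
                    {
                        "variable": var,
                        "factor": factor,
                        "stratum": level,
                        "n": len(groups[level]),
                        "median": m,
                        "q1": lo,
                        "q3": hi,
                        "letter": letters[level],
                    }
                )
            summary_rows.append(
                {
                    "variable": var,
                    "factor": factor,
                    "stratum": "national",
                    "n": len(df),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "letter": "",
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a registry file and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = (
        load_composition_table(config.composition_path)
        if config.composition_path
        else default_composition_table()
    )
    prices = (
        PriceTable.from_csv(config.price_path)
        if config.price_path
        else default_price_table()
    )
    standards = (
        load_standards(config.standards_path)
        if config.standards_path
        else default_standards()
    )

    registry = parse_registry(config.registry_path)
    municipalities = {m.municipality_id: m for m in registry.municipalities}
    kept, excluded = ingest_registry(
        registry,
        table,
        prices,
        similarity_floor=config.similarity_floor,
        item_ceiling_kg=config.item_ceiling_kg,
        basket_ceiling_kg=config.basket_ceiling_kg,
        densities=config.densities or None,
    )

    profile_rows, group_rows, zero_energy = [], [], []
    approx_log = {"weight_approximated": [], "similarity_matched": []}
    for basket in kept:
        muni = municipalities[basket.municipality_id]
        try:
            prof = basket_profile(basket)
        except UndefinedDistributionError:
            zero_energy.append(basket.municipality_id)
            continue
        profile_rows.append(
            {
                "municipality_id": basket.municipality_id,
                "domain": muni.domain,
                "budget_group": muni.budget_group,
                "energy_kcal": prof.energy_kcal,
                "table_energy_kcal": prof.table_energy_kcal,
                "protein_g": prof.protein_g,
                "fat_g": prof.fat_g,
                "carb_g": prof.carb_g,
                "pct_protein": prof.pct_protein,
                "pct_fat": prof.pct_fat,
                "pct_carb": prof.pct_carb,
            }
        )
        gq = group_quantities(basket)
        group_rows.append(
            {
                "municipality_id": basket.municipality_id,
                "domain": muni.domain,
                "budget_group": muni.budget_group,
                **{f"{g}_kg": gq[g] for g in gq},
            }
        )
        for item in basket.items:
            if item.weight_approximated:
                approx_log["weight_approximated"].append(item.entry.group)
            if item.similarity_matched:
                approx_log["similarity_matched"].append(item.entry.group)

    profiles = pd.DataFrame(profile_rows)
    group_kg = pd.DataFrame(group_rows)

    exclusion_counts: dict[str, int] = {}
    for exc in excluded:
        exclusion_counts[exc.reason] = exclusion_counts.get(exc.reason, 0) + 1
    if zero_energy:
        exclusion_counts["zero_energy"] = len(zero_energy)
    flow = {
        "municipalities_in": len(municipalities),
        "analyzed": len(profiles),
        "excluded": exclusion_counts,
        "parse_rejects": len(registry.rejects),
    }
    flow_conserved = flow["municipalities_in"] == flow["analyzed"] + sum(
        exclusion_counts.values()
    )

    if profiles.empty:
        adequacy = pd.DataFrame()
        dist_summary = pd.DataFrame()
        gq_summary = pd.DataFrame()
        tests = pd.DataFrame()
        note = "no baskets survived inclusion"
    else:
        classified = classification_frame(profiles, standards)
        blocks = []
        for stratum_col in ("domain", "budget_group"):
            blk = adequacy_summary(
                classified, stratum_col, weights=config.expansion_weights
            )
            blk.insert(0, "factor", stratum_col)
            blocks.append(blk)
        national = classified.assign(national="national")
        blk = adequacy_summary(national, "national")
        blk.insert(0, "factor", "national")
        blocks.append(blk)
        adequacy = pd.concat(blocks, ignore_index=True)

        dist_summary, dist_tests = _stratified_summary(
            profiles, ["pct_protein", "pct_fat", "pct_carb"], config.alpha
        )
        gq_summary, gq_tests = _stratified_summary(
            group_kg, [f"{g}_kg" for g in CORE_GROUPS], config.alpha
        )
        tests = pd.concat([dist_tests, gq_tests], ignore_index=True)
        note = ""

    def _count_groups(kinds: list[str]) -> dict:
        total = len(kinds)
        counts = pd.Series(kinds).value_counts().to_dict() if kinds else {}
        return {"total": total, "by_group": {k: int(v) for k, v in counts.items()}}

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "flow": flow,
        "flow_conserved": flow_conserved,
        "approximations": {
            k: _count_groups(v) for k, v in approx_log.items()
        },
        "standards": sorted(standards),
        "note": note,
    }

    profiles.to_csv(out / "profiles.csv", index=False)
    group_kg.to_csv(out / "group_quantities.csv", index=False)
    adequacy.to_csv(out / "adequacy_summary.csv", index=False)
    dist_summary.to_csv(out / "distribution_summary.csv", index=False)
    gq_summary.to_csv(out / "group_quantity_summary.csv", index=False)
    tests.to_csv(out / "tests.csv", index=False)
    with open(out / "flow.json", "w") as fh:
        json.dump(flow, fh, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        profiles=profiles,
        group_kg=group_kg,
        adequacy=adequacy,
        distribution_summary=dist_summary,
        group_quantity_summary=gq_summary,
        flow=flow,
        manifest=manifest,
    )
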