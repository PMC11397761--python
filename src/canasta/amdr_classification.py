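"""Classification of caloric distributions against AMDR standards.

An Acceptable Macronutrient Distribution Range (AMDR) standard gives, per
macronutrient, the band of percent-of-total-energy compatible with a balanced
ration.  Two standards ship by default: INCAP (protein 10–15 %, fat 20–25 %,
carbohydrate 60–70 %) and INDECI (protein 10–15 %, fat 20–35 %, carbohydrate
50–65 %).  A percentage strictly below the band is a deficit, strictly above
is an excess, and the band itself — endpoints included — is adequate; a basket
is overall adequate when all three macronutrients are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .nutrient_accounting import MACRONUTRIENTS, NutrientProfile

DEFICIT = "deficit"
ADEQUATE = "adequate"
EXCESS = "excess"
LABELS = (DEFICIT, ADEQUATE, EXCESS)


@dataclass(frozen=True)
class AMDRStandard:
    name: str
    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for macro in MACRONUTRIENTS:
            if macro not in self.bounds:
                raise ValueError(f"standard {self.name}: missing bounds for {macro}")
            low, high = self.bounds[macro]
            if not (0 <= low < high <= 100):
                raise ValueError(
                    f"standard {self.name}: invalid {macro} bounds [{low}, {high}]"
                )


def load_standards(path: str | Path) -> dict[str, AMDRStandard]:
    """Load AMDR standards from a JSON list of {name, bounds} objects."""
    with open(path) as fh:
        raw = json.load(fh)
    standards = {}
    for item in raw:
        std = AMDRStandard(
            name=item["name"],
            bounds={m: tuple(b) for m, b in item["bounds"].items()},
        )
        standards[std.name] = std
    return standards


def default_standards() -> dict[str, AMDRStandard]:
    """The packaged INCAP and INDECI standards."""
    with resources.as_file(
        resources.files("canasta.data").joinpath("amdr_standards.json")
    ) as p:
        return load_standards(p)


@dataclass(frozen=True)
class MacroClassification:
    standard: str
    labels: dict[str, str]  # macronutrient -> deficit | adequate | excess

    @property
    def overall_adequate(self) -> bool:
        return all(lbl == ADEQUATE for lbl in self.labels.values())


def classify_pct(pct: float, low: float, high: float) -> str:
    """Deficit iff pct < low, excess iff pct > high, else adequate."""
    if pct < low:
        return DEFICIT
    if pct > high:
        return EXCESS
    return ADEQUATE


def classify(profile: NutrientProfile, standard: AMDRStandard) -> MacroClassification:
    """Label each macronutrient of a profile under one AMDR standard."""
    labels = {}
    for macro in MACRONUTRIENTS:
        low, high = standard.bounds[macro]
        labels[macro] = classify_pct(profile.pct(macro), low, high)
    return MacroClassification(standard=standard.name, labels=labels)


def adequacy_summary(
    classified: pd.DataFrame,
    stratum_col: str,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-stratum deficit/excess proportions and overall adequacy.

    ``classified`` needs one row per basket with columns ``standard``,
    ``<macro>_label`` for each macronutrient, ``overall_adequate`` and the
    stratum column.  ``weights`` optionally maps stratum -> expansion weight
    (N_h/n_h); unweighted counts are used otherwise.  Empty strata are simply
    absent from the output.  Percentages are on a 0–100 scale.
    """
    rows = []
    for (standard, stratum), grp in classified.groupby(["standard", stratum_col]):
        w = weights.get(str(stratum), 1.0) if weights else 1.0
        n = len(grp)
        row = {
            "standard": standard,
            "stratum": stratum,
            "n": n,
            "weighted_n": n * w,
        }
        for macro in MACRONUTRIENTS:
            labels = grp[f"{macro}_label"]
            row[f"{macro}_deficit_pct"] = (labels == DEFICIT).mean() * 100.0
            row[f"{macro}_excess_pct"] = (labels == EXCESS).mean() * 100.0
        row["overall_adequate_pct"] = grp["overall_adequate"].mean() * 100.0
        rows.append(row)
    return pd.DataFrame(rows)


def classification_frame(
    profiles: pd.DataFrame, standards: dict[str, AMDRStandard]
) -> pd.DataFrame:
    """Classify every profile row under every standard.

    ``profiles`` needs ``pct_protein``, ``pct_fat``, ``pct_carb`` columns; all
    other columns (municipality id, strata) are carried through.  Returns one
    row per profile per standard.
    """
    out = []
    for name in sorted(standards):
        std = standards[name]
        block = profiles.copy()
        block["standard"] = name
        for macro in MACRONUTRIENTS:
            low, high = std.bounds[macro]
            pct = block[f"pct_{macro}"]
            labels = pd.Series(ADEQUATE, index=block.index)
            labels[pct < low] = DEFICIT
            labels[pct > high] = EXCESS
            block[f"{macro}_label"] = labels
        block["overall_adequate"] = (
            (block[[f"{m}_label" for m in MACRONUTRIENTS]] == ADEQUATE).all(axis=1)
        )
        out.append(block)
    return pd.concat(out, ignore_index=True)
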