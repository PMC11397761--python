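"""Simulate the basket registry for the selected municipalities.

Generates registry rows (one per food item per basket variant) for the
municipalities selected in 01, at the default study conditions: national
median quantities per food group, 53 % of municipalities with multiple basket
variants, 10 % of items registered in "units" (concentrated in meats), 2 % of
baskets with an extreme quantity, and occasional variant spellings of canned
fish.  Writes scratch/registry.csv with a truth-label sidecar.
"""

import json
from pathlib import Path

import canasta as c
from canasta.basket_ingest import default_price_table
from canasta.synthetic_data import GeneratorConfig

SEED = 0
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"


def main() -> None:
    with open(SCRATCH / "selection.json") as fh:
        selection = json.load(fh)
    chosen = {mid for ids in selection["selected"].values() for mid in ids}

    config = GeneratorConfig(n_municipalities=1874, seed=selection["seed"])
    frame = [m for m in c.generate_frame(config) if m.municipality_id in chosen]
    rows, truth = c.generate_registry(
        frame, config, c.default_composition_table(), default_price_table(),
        seed=selection["seed"] + 2,
    )
    c.write_registry(rows, SCRATCH / "registry.csv", truth)

    n_baskets = rows.groupby("municipality_id")["basket_id"].nunique()
    print(f"registry: {len(rows)} item rows, {len(frame)} municipalities")
    print(f"municipalities with >1 basket variant: {(n_baskets > 1).mean():.1%}")
    print(
        f"injected: {len(truth['unit_items'])} unit records, "
        f"{len(truth['extreme_baskets'])} extreme baskets, "
        f"{len(truth['alias_items'])} alias spellings"
    )
    print("wrote scratch/registry.csv (+ .truth.json)")


if __name__ == "__main__":
    main()
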