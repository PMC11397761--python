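"""Survey design: finite-population sample size and stratified selection.

Computes the net and gross sample sizes for estimating a proportion over a
frame of 1874 municipalities (p = 0.5, 95 % confidence, ±5 points, +30 % for
registry loss), draws a synthetic frame, and selects the gross sample by
proportional stratified sampling over the four geographic domains.

Writes the selection to scratch/ (consumed by 02) and a small design summary
to results/design_summary.json.
"""

import json
from pathlib import Path

import canasta as c
from canasta.stratified_stats import proportional_allocation
from canasta.synthetic_data import GeneratorConfig

SEED = 0
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    design = c.SamplingDesign(
        population_size=1874,
        expected_p=0.5,
        confidence=0.95,
        margin=0.05,
        loss_fraction=0.30,
    )
    net, gross = c.sample_size(design)
    print(f"frame: {design.population_size} municipalities")
    print(f"net sample size (FPC-corrected): {net}")
    print(f"gross sample size (+30% loss): {gross}")

    config = GeneratorConfig(n_municipalities=1874, seed=SEED)
    frame = c.generate_frame(config)
    by_domain: dict[str, list[str]] = {}
    for m in frame:
        by_domain.setdefault(m.domain, []).append(m.municipality_id)
    allocation = proportional_allocation(
        {d: len(ids) for d, ids in by_domain.items()}, gross
    )
    selected = c.stratified_select(by_domain, allocation, seed=SEED + 1)
    print("proportional allocation by domain:", allocation)

    with open(SCRATCH / "selection.json", "w") as fh:
        json.dump({"seed": SEED, "selected": selected}, fh, indent=1)
    summary = {
        "frame_size": design.population_size,
        "net_sample_size": net,
        "gross_sample_size": gross,
        "allocation": allocation,
    }
    with open(RESULTS / "design_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"selection of {sum(allocation.values())} municipalities written to scratch/")


if __name__ == "__main__":
    main()
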