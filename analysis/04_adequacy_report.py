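"""Report adequacy of the simulated baskets against both AMDR standards.

Reads the pipeline outputs (03) and prints the headline adequacy story: the
share of baskets with deficit or excess per macronutrient, and the share with
all three macronutrients inside the acceptable range, nationally and by
stratum — the numbers a surveillance team would act on.  Also prints the
median (IQR) caloric distribution with compact significance letters from the
Kruskal–Wallis / Dunn comparisons.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    adequacy = pd.read_csv(RESULTS / "adequacy_summary.csv")
    dist = pd.read_csv(RESULTS / "distribution_summary.csv")

    national = adequacy[adequacy["factor"] == "national"]
    print("=== national adequacy ===")
    for _, row in national.iterrows():
        print(
            f"{row['standard']}: protein deficit {row['protein_deficit_pct']:.1f}%, "
            f"carb excess {row['carb_excess_pct']:.1f}%, "
            f"fat excess {row['fat_excess_pct']:.1f}%, "
            f"fully adequate {row['overall_adequate_pct']:.1f}%"
        )

    print("\n=== fully adequate baskets by stratum ===")
    strata = adequacy[adequacy["factor"] != "national"]
    table = strata.pivot_table(
        index=["factor", "stratum"],
        columns="standard",
        values="overall_adequate_pct",
    ).round(1)
    print(table.to_string())

    print("\n=== caloric distribution, median (IQR) with letters ===")
    for variable, sub in dist.groupby("variable"):
        rows = []
        for _, r in sub.iterrows():
            letter = "" if pd.isna(r["letter"]) else str(r["letter"])
            rows.append(
                f"{r['factor']}/{r['stratum']}: {r['median']:.1f} "
                f"({r['q1']:.1f}-{r['q3']:.1f}) {letter}".rstrip()
            )
        print(f"{variable}:")
        for line in rows:
            print("  " + line)


if __name__ == "__main__":
    main()
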