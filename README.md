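# canasta

Nutrient accounting and macronutrient-adequacy assessment for emergency
food-basket registries.

During large food-assistance operations, municipalities register the baskets
they distribute as free-text item lists — "arroz pilado, 13 kg; conserva de
atún, 6 units; aceite vegetal, 2 L" — in an administrative database, not a
nutrition survey. `canasta` turns such registries into an auditable answer to
the question a surveillance team actually has: **is the ration nutritionally
balanced?** It is written for nutrition-surveillance analysts and
epidemiologists evaluating basic-food-basket (canasta básica) programs.

## What it computes

For every municipality's basket (the variant distributed to the most
beneficiaries, among those with ≥ 3 distinct foods and no implausible
quantities):

1. **Nutrient accounting.** Each item is matched to a food-composition table
   (exactly, or by a token-set *similar-food* approximation for products like
   canned tuna that lack their own code); items registered in "units" are
   converted to mass through mean wholesale/retail market prices. Available
   energy uses the Atwater general factors,

   *E* = 4 *P* + 9 *F* + 4 *C*  (kcal; *P*, *F*, *C* in grams),

   and the caloric distribution is each macronutrient's share of *E*:
   %P = 4*P*/*E* × 100, %F = 9*F*/*E* × 100, %C = 4*C*/*E* × 100.

2. **AMDR classification.** Each percentage is labelled against an Acceptable
   Macronutrient Distribution Range standard: *deficit* if strictly below the
   band, *excess* if strictly above, *adequate* inside it (bounds inclusive).
   Two standards ship by default — INCAP (protein 10–15 %, fat 20–25 %,
   carbohydrate 60–70 %) and INDECI (protein 10–15 %, fat 20–35 %,
   carbohydrate 50–65 %) — and others can be added as JSON.

3. **Stratified summaries.** Median (IQR) caloric distribution and kilograms
   per food group by geographic domain and budget group, compared with
   Kruskal–Wallis tests and all-pairs Dunn post-hoc z tests (Holm-adjusted)
   rendered as compact letter displays; deficit/excess proportions and the
   share of fully adequate baskets per stratum and standard.

It also includes the survey-design utilities (finite-population sample size
with the n₀ = z²p(1−p)/d² correction, stratified without-replacement
selection) and a synthetic registry generator that emulates the registries'
statistical structure — multi-basket municipalities, unit-denominated
records concentrated in canned fish, extreme data-entry errors — with truth
labels, so the whole chain is testable without any external data.

## Worked example

Classify a basket containing 385 g protein, 625 g fat and 3125 g carbohydrate:

```bash
canasta classify --protein-g 385 --fat-g 625 --carb-g 3125
```

```json
{
 "energy_kcal": 19665.0,
 "pct": {"protein": 7.83, "fat": 28.60, "carb": 63.56},
 "classification": {
  "INCAP":  {"protein": "deficit", "fat": "excess",   "carb": "adequate", "overall_adequate": false},
  "INDECI": {"protein": "deficit", "fat": "adequate", "carb": "adequate", "overall_adequate": false}
 }
}
```

The basket provides 19 665 kcal of which 7.8 % comes from protein — below
every standard's 10 % floor, so it is protein-deficient regardless of the
reference; its 28.6 % of energy from fat is an excess under INCAP's tighter
20–25 % band but acceptable under INDECI's 20–35 %.

Survey design for a frame of 1874 municipalities:

```bash
canasta sample-size -N 1874 --loss 0.30
# net sample size: 319
# gross sample size (with 30% loss): 415
```

## The analysis

The `analysis/` scripts run the full study on a synthetic registry, in order:

| script | what it does |
|---|---|
| `01_design_sample.py` | sample size (319 net / 415 gross) and stratified selection from a 1874-municipality frame |
| `02_simulate_registry.py` | simulates the item-level registry for the selected municipalities, with injected data-entry errors |
| `03_run_pipeline.py` | ingest → nutrient accounting → AMDR classification → stratified summaries |
| `04_adequacy_report.py` | prints the adequacy story and the median (IQR) tables with significance letters |

Bulky intermediates go to `scratch/`; summary tables land in `results/`.
Equivalently, `canasta simulate` and `canasta analyze` run the same stages
from the shell.

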