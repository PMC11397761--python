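# Methods

This note records the model, the defaults and the design decisions behind
`canasta`, in the order the pipeline applies them.

## Registry model and ingestion

A registry row is one food item of one basket variant of one municipality
(`municipality_id, domain, budget_group, population, basket_id,
beneficiaries, food_name, quantity, unit, unit_price`). Municipalities are
stratified by four geographic domains (Metropolitan Lima, rest of the coast,
highlands, jungle) and four budget groups A–D, defined by transfer size
(A ≈ 50 000 soles ≈ US$14 000 up to D > 500 000 soles). The implied exchange
rate 50 000/14 000 ≈ 3.571 soles per US$ is the one used for all currency
conversions.

When a municipality registers several basket variants, the analysis keeps the
variant with the most beneficiaries (ties break to the smallest basket id, so
ingestion is deterministic and order-independent).

**Units.** `kg` and `g` convert directly; `L` and `mL` convert at a
configurable density per food group, default 1.0 g/mL for every group. This
overstates oil mass by ~8 %, but it keeps litre-registered quantities
numerically equal to the reported "kg-or-L" group totals, which is how such
registries are conventionally summarised; per-group overrides are available
in `PipelineConfig.densities`.

**Unit-denominated items** (typically canned fish registered as "6 units")
convert through market prices: mass_g = quantity × (unit_price / mean of
wholesale and retail price per kg) × 1000. When the registered spelling has
no price entry, the price of the similarity-matched food is used. Items that
still fail (no price, no usable unit price) count as unresolved.

**Inclusion/exclusion.** A basket is analysed only if (a) at most 20 % of its
raw items are unresolved, (b) it has ≥ 3 distinct foods, and (c) no single
item exceeds 100 kg and the basket total does not exceed 500 kg. The mass
ceilings operationalise "implausibly extreme quantity"; no authoritative
cutoff exists for these registries, so the defaults are deliberately generous
(an order of magnitude above any plausible ration) and configurable. Every
exclusion carries a machine-readable reason (`unresolved_items`,
`too_few_foods`, `extreme_value`; checked in that order, one reason per
basket), and the run manifest asserts flow conservation: municipalities in =
analysed + excluded by reason.

## Name resolution

Free-text names are normalised (lowercase, accents and punctuation stripped,
whitespace collapsed) and matched exactly against the composition table's
name index. Failing that, the closest entry by a token-set similarity — the
best `difflib` ratio among the shared-token string and the full sorted-token
strings — wins, restricted to a declared food group when a hint is given,
with a floor of 0.6 and ties broken to the smallest code. The floor is the
point at which shared-token matches like "conserva de atún en aceite" →
"conserva de pescado en aceite" (≈ 0.9) clearly separate from cross-group
collisions like "… en aceite" → "aceite vegetal" (≈ 0.57). Unresolved names
are surfaced to the caller; the pipeline counts them toward the basket's
unresolved fraction rather than guessing.

The packaged composition table is a synthetic stand-in for a national
food-composition reference: 40 common basket foods spanning the ten food
groups of the national food guide (sugars, meats, cereals, oils, dairy,
legumes, fruits, eggs, vegetables, tubers), with per-100 g energy, protein,
fat and carbohydrate transcribed from public food-composition references.
The packaged price table is likewise synthetic but price-coherent with it.

## Nutrient accounting

Item nutrients scale linearly in mass from the per-100 g values. Basket
energy is the Atwater sum E = 4P + 9F + 4C; the caloric distribution is each
macronutrient's energy share of E, so the three percentages sum to exactly
100. The composition table's own energy column is reported alongside
(`table_energy_kcal`) but is deliberately not the denominator: table energies
embed rounding and non-Atwater conventions that would make the shares sum
away from 100. Alcohol and fibre energy are ignored. A basket with zero
Atwater energy raises rather than silently reporting zeros.

## AMDR classification

A standard is a set of [low, high] percent-of-energy bands. Labels follow
strict outer inequalities: deficit iff pct < low, excess iff pct > high,
adequate on the closed band — a percentage exactly at a bound is adequate.
The full label set (including protein excess, rarely observed in practice) is
implemented for every macronutrient. A basket is *overall adequate* iff all
three labels are adequate. Standards live in JSON
(`src/canasta/data/amdr_standards.json`), so further references (e.g. WHO)
are a config edit, not a code change. Useful structural facts, enforced by
tests: the two defaults share the protein band, and INCAP's fat band [20, 25]
nests inside INDECI's [20, 35], so INCAP-fat-adequate implies
INDECI-fat-adequate; the carbohydrate bands ([60, 70] vs [50, 65]) merely
overlap, so no nesting holds there.

Adequacy summaries report per-stratum proportions; optional expansion weights
(N_h/n_h per stratum) can be supplied, but no claim is made that weighted
counts reproduce any particular population expansion, whose weighting would
be survey-specific.

## Survey design and statistics

* **Sample size:** n₀ = z²p(1−p)/d², corrected as n = n₀/(1 + (n₀−1)/N),
  rounded up; the gross size multiplies by (1 + loss) and rounds half-up.
  z is the two-sided normal quantile rounded to two decimals (1.96 at 95 %),
  the convention under which the worked design (N = 1874, p = 0.5, d = 0.05,
  30 % loss) gives 319 net / 415 gross.
* **Selection:** without-replacement uniform draws within strata, sorted
  stratum order, a single seeded generator; largest-remainder proportional
  allocation by default.
* **Quartiles:** linear interpolation (numpy default). Other conventions
  (e.g. SPSS's weighted-average HAVERAGE) differ by O(1/n) and are
  immaterial at these sample sizes.
* **Kruskal–Wallis:** scipy's tie-corrected H with a χ²(k−1) p-value. The
  all-identical sample is taken as H = 0, p = 1 (no evidence of group
  differences) rather than an error.
* **Post-hoc:** all-pairs Dunn z tests on mean ranks with tie correction,
  Holm-adjusted by default (Bonferroni available). Letters come from the
  insert-and-absorb construction, giving the usual guarantee both ways: two
  groups share a letter iff their adjusted pairwise test is not significant
  at α. Dunn's all-pairs rank comparison is the appropriate follow-up to a
  Kruskal–Wallis rejection when every pair is of interest; control-versus-
  treatment procedures (Dunnett) do not produce all-pairs letter groupings
  and are out of scope.

## Synthetic registry generator

The generator defines the study conditions under which the pipeline is
exercised and its parameters are *not* tuned per run:

* Frame of 1874 municipalities; stratum weights uniform over the four domains
  and four budget groups (the real joint distribution of domain × budget is
  not public; uniform is documented as synthetic, not estimated).
* Six core food groups are always present with per-basket totals drawn
  log-normal, parameterised by national median targets (sugars 5.0, meats
  0.7, cereals 13.1, oils 2.0, dairy 1.6, legumes 2.0 kg) and σ =
  ln(q3/q1)/1.349 from the corresponding quartiles. Positivity and right
  skew match observed basket quantities. (For legumes the reported quartiles
  are incompatible with any continuous log-normal — q1 equals the median, an
  artefact of whole-kg registration — so only the quartile *ratio* is
  honoured.) A group's total is split across one or, with probability 0.35,
  two foods of the group. Four optional groups (fruits, eggs, vegetables,
  tubers) appear with probability 0.15 each, ~1 kg, matching their rarity in
  real baskets.
* Domain and budget effects are multiplicative shifts on group medians whose
  product over the levels of each factor is 1, so national medians stay at
  the targets while reproducing the qualitative stratum ordering (Lima-like
  stratum: more meat, less sugar; lowest-budget stratum: more sugar, cereals,
  oils, dairy and legumes; highest-budget: more meat, fewer cereals).
* Error injection, all truth-labelled: 53 % of municipalities get 2–3 basket
  variants; 10 % of items are emitted as "units" with a coherent price
  (recoverable mass), selected with meats-weighted probabilities targeting a
  52 % meats share in expectation; 2 % of baskets receive one extreme
  quantity drawn in 150–1000 kg, guaranteeing detection by the 100 kg
  ceiling; 5 % of meats items use a variant spelling resolvable only by
  similarity.

**Implied distribution targets.** The caloric-distribution medians a
configuration implies have no closed form (medians of ratios of mixtures), so
they are *defined* by a deterministic direct simulation of the same
generative model (n = 50 000, fixed internal seed), bypassing CSV
serialisation and ingest. Parameter-recovery checks then compare the full
pipeline route — emit CSV, parse, resolve names, convert units, select
baskets, account — against these targets: two independent routes through the
same model. At the checked sizes the agreement bands (±10 % on kg medians at
n = 366; ±0.5 percentage points on distribution medians at n = 1000 with
error injection off) sit several Monte-Carlo standard errors above the
expected sampling noise.

What the generator does **not** emulate: item-level price econometrics,
seasonal or spatial correlation between municipalities, within-group food
preferences beyond uniform choice, or the real (unpublished) domain × budget
distribution. Passing recovery tests therefore shows the pipeline is a
faithful inverse of this structural model, not that any particular real-world
registry satisfies the model.

## Problem sizes and determinism

The test suite exercises the pipeline at 80–1000 municipalities and the
acceptance script at the full sampling design (frame 1874, gross sample 415),
sizes at which every stage's Monte-Carlo error is well inside the asserted
tolerances while the whole suite runs in seconds. Every stochastic component
takes an explicit seed; registry emission is byte-identical under a fixed
seed, and the pipeline is idempotent (byte-identical outputs) under fixed
inputs, as tested.

## Known limitations

* Composition and price tables are small synthetic stand-ins; real analyses
  should mount a national composition table via `PipelineConfig` paths.
* The 1 g/mL default density conflates litres and kilograms for oils.
* No per-capita or per-day scaling: baskets are assessed as delivered, not
  against household energy requirements.
* Micronutrients, cooked/raw retention factors and normality diagnostics are
  out of scope.
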