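import math

import pytest
from hypothesis import given, settings, strategies as st

from canasta.basket_ingest import (
    EXTREME_VALUE,
    TOO_FEW_FOODS,
    RawItemRecord,
    UnresolvedItemError,
    apply_inclusion_exclusion,
    approximate_weight,
    ingest_registry,
    parse_registry,
    resolve_basket,
    select_basket,
    soles_to_usd,
)
from conftest import make_basket


def unit_record(**kw):
    defaults = dict(
        municipality_id="M1",
        basket_id="B1",
        food_name="conserva de pescado en aceite",
        quantity=1.0,
        unit="unit",
        beneficiaries=100,
        unit_price=5.0,
    )
    return RawItemRecord(**{**defaults, **kw})


class TestParseRegistry:
    def test_round_trip_municipalities(self, write_registry_csv):
        rows = [
            {"municipality_id": f"M{i}", "basket_id": "B1"} for i in range(10)
        ]
        parsed = parse_registry(write_registry_csv(rows))
        assert len(parsed.municipalities) == 10
        assert len(parsed.records) == 10
        assert parsed.rejects == []

    def test_unknown_unit_rejected_with_reason(self, write_registry_csv):
        parsed = parse_registry(
            write_registry_csv([{"unit": "docena"}, {"unit": "kg"}])
        )
        assert len(parsed.records) == 1
        assert len(parsed.rejects) == 1
        assert "unknown unit" in parsed.rejects[0]["reason"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        parsed = parse_registry(p)
        assert parsed.records == [] and parsed.municipalities == []

    def test_nonpositive_quantity_rejected(self, write_registry_csv):
        parsed = parse_registry(write_registry_csv([{"quantity": 0.0}]))
        assert parsed.records == [] and len(parsed.rejects) == 1


class TestApproximateWeight:
    def test_single_unit_arithmetic(self, prices):
        # mean(wholesale 12, retail 15) = 13.5 soles/kg
        rec = unit_record(quantity=1.0, unit_price=6.75)
        assert approximate_weight(rec, prices) == pytest.approx(500.0)

    def test_linear_in_quantity(self, prices):
        one = approximate_weight(unit_record(quantity=1.0, unit_price=2.5), prices)
        four = approximate_weight(unit_record(quantity=4.0, unit_price=2.5), prices)
        assert four == pytest.approx(4 * one)

    def test_missing_price_unresolved(self, prices):
        rec = unit_record(food_name="producto desconocido")
        with pytest.raises(UnresolvedItemError):
            approximate_weight(rec, prices)

    def test_missing_unit_price_unresolved(self, prices):
        rec = unit_record(unit_price=None)
        with pytest.raises(UnresolvedItemError):
            approximate_weight(rec, prices)

    @settings(deadline=None)
    @given(
        price=st.floats(0.5, 50),
        quantity=st.floats(0.5, 20),
        bump=st.floats(0.1, 5),
    )
    def test_strictly_increasing_in_price_and_quantity(self, prices, price, quantity, bump):
        base = approximate_weight(
            unit_record(quantity=quantity, unit_price=price), prices
        )
        assert (
            approximate_weight(
                unit_record(quantity=quantity, unit_price=price + bump), prices
            )
            > base
        )
        assert (
            approximate_weight(
                unit_record(quantity=quantity + bump, unit_price=price), prices
            )
            > base
        )


class TestSelectBasket:
    def test_most_beneficiaries_wins(self):
        assert select_basket({"b1": 500, "b2": 1200}) == "b2"

    def test_single_basket(self):
        assert select_basket({"b9": 10}) == "b9"

    def test_tie_breaks_to_smallest_id(self):
        assert select_basket({"b2": 800, "b1": 800}) == "b1"

    def test_invariant_to_ordering(self):
        a = {"x": 5, "y": 9, "z": 9}
        b = dict(reversed(list(a.items())))
        assert select_basket(a) == select_basket(b) == "y"


class TestInclusionExclusion:
    def test_too_few_foods(self, table):
        basket = make_basket(table, {"F001": 5.0, "F007": 2.0})
        kept, excluded = apply_inclusion_exclusion([(basket, [])])
        assert kept == [] and excluded[0].reason == TOO_FEW_FOODS

    def test_extreme_item_excluded(self, table):
        basket = make_basket(table, {"F001": 600.0, "F007": 2.0, "F016": 1.0})
        kept, excluded = apply_inclusion_exclusion([(basket, [])])
        assert kept == [] and excluded[0].reason == EXTREME_VALUE

    def test_clean_basket_kept(self, table):
        basket = make_basket(
            table, {"F001": 10.0, "F007": 2.0, "F016": 1.0, "F023": 2.0, "F019": 1.5}
        )
        kept, excluded = apply_inclusion_exclusion([(basket, [])])
        assert len(kept) == 1 and excluded == []

    def test_unresolved_fraction_excludes(self, table):
        basket = make_basket(table, {"F001": 5.0, "F007": 2.0, "F016": 1.0})
        rejects = [{"food_name": "???", "reason": "x"}] * 2  # 2 of 5 raw items
        kept, excluded = apply_inclusion_exclusion([(basket, rejects)])
        assert kept == [] and excluded[0].reason == "unresolved_items"

    def test_partition(self, table):
        baskets = [
            (make_basket(table, {"F001": 5.0}), []),
            (make_basket(table, {"F001": 5.0, "F007": 2.0, "F016": 1.0}), []),
            (make_basket(table, {"F001": 600.0, "F007": 2.0, "F016": 1.0}), []),
        ]
        kept, excluded = apply_inclusion_exclusion(baskets)
        assert len(kept) + len(excluded) == len(baskets)


class TestResolveBasket:
    def test_flags_carried(self, table, prices):
        records = [
            unit_record(food_name="arroz pilado", unit="kg", quantity=5.0),
            unit_record(food_name="conserva de atun en aceite", unit="kg", quantity=0.7),
            unit_record(quantity=2.0, unit_price=6.75),
        ]
        basket, rejects = resolve_basket(records, table, prices)
        assert rejects == []
        flags = {
            (it.weight_approximated, it.similarity_matched) for it in basket.items
        }
        assert (False, False) in flags  # plain rice
        assert (False, True) in flags  # alias canned tuna
        assert (True, False) in flags  # unit record

    def test_ingest_selects_largest_basket(self, write_registry_csv, table, prices):
        rows = []
        for bid, ben in (("B1", 100), ("B2", 900)):
            for food in ("arroz pilado", "azucar rubia", "aceite vegetal"):
                rows.append(
                    {"basket_id": bid, "beneficiaries": ben, "food_name": food}
                )
        parsed = parse_registry(write_registry_csv(rows))
        kept, excluded = ingest_registry(parsed, table, prices)
        assert len(kept) == 1 and kept[0].basket_id == "B2"


def test_currency_conversion_implied_rate():
    # budget-group equivalence: 50,000 soles <-> US$14,000
    assert soles_to_usd(50_000) == pytest.approx(14_000)
    assert math.isclose(soles_to_usd(213e6) / 1e6, 59.64, abs_tol=0.005)
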