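import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from canasta.stratified_stats import (
    SamplingDesign,
    compact_letter_display,
    dunn_posthoc,
    kruskal_wallis,
    median_iqr,
    posthoc_letters,
    proportional_allocation,
    sample_size,
    stratified_select,
)


class TestSampleSize:
    def test_loss_zero_identity(self):
        net, gross = sample_size(SamplingDesign(population_size=1000))
        assert net == gross

    def test_invalid_margin(self):
        with pytest.raises(ValueError):
            SamplingDesign(population_size=1000, margin=0)

    @pytest.mark.parametrize("n_small,n_big", [(500, 5000), (1874, 50000)])
    def test_monotone_in_population(self, n_small, n_big):
        small, _ = sample_size(SamplingDesign(population_size=n_small))
        big, _ = sample_size(SamplingDesign(population_size=n_big))
        assert small <= big

    def test_monotone_in_confidence_and_margin(self):
        base, _ = sample_size(SamplingDesign(population_size=5000))
        higher_conf, _ = sample_size(
            SamplingDesign(population_size=5000, confidence=0.99)
        )
        wider_margin, _ = sample_size(
            SamplingDesign(population_size=5000, margin=0.10)
        )
        assert higher_conf >= base >= wider_margin

    def test_stratum_sizes_must_sum(self):
        with pytest.raises(ValueError):
            SamplingDesign(population_size=100, stratum_sizes={"a": 10, "b": 20})


class TestStratifiedSelect:
    FRAME = {s: [f"{s}{i}" for i in range(25)] for s in "abcd"}

    def test_counts_per_stratum(self):
        sample = stratified_select(self.FRAME, {s: 5 for s in "abcd"}, seed=0)
        assert sum(len(v) for v in sample.values()) == 20
        assert all(len(v) == 5 for v in sample.values())

    def test_deterministic_under_seed(self):
        a = stratified_select(self.FRAME, {s: 5 for s in "abcd"}, seed=42)
        b = stratified_select(self.FRAME, {s: 5 for s in "abcd"}, seed=42)
        assert a == b

    def test_without_replacement(self):
        sample = stratified_select(self.FRAME, {"a": 25}, seed=1)
        assert len(set(sample["a"])) == 25

    def test_overallocation_names_stratum(self):
        with pytest.raises(ValueError, match="'b'"):
            stratified_select(self.FRAME, {"b": 30}, seed=0)

    def test_proportional_allocation_sums(self):
        alloc = proportional_allocation({"a": 100, "b": 250, "c": 650}, 37)
        assert sum(alloc.values()) == 37
        assert alloc["c"] > alloc["b"] > alloc["a"]


class TestMedianIqr:
    def test_small_example(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)

    def test_constant_sample(self):
        assert median_iqr([7.5] * 10) == (7.5, 7.5, 7.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            median_iqr([])

    @settings(deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    def test_against_sorting_oracle(self, values):
        def quantile_oracle(xs, q):
            # linear interpolation over the sorted sample, from first principles
            ys = sorted(xs)
            h = (len(ys) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(ys) - 1)
            return ys[lo] + (h - lo) * (ys[hi] - ys[lo])

        med, q1, q3 = median_iqr(values)
        assert med == pytest.approx(quantile_oracle(values, 0.5), rel=1e-9, abs=1e-9)
        assert q1 == pytest.approx(quantile_oracle(values, 0.25), rel=1e-9, abs=1e-9)
        assert q3 == pytest.approx(quantile_oracle(values, 0.75), rel=1e-9, abs=1e-9)


class TestKruskalWallis:
    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        pooled = rng.normal(size=60)
        h1, _ = kruskal_wallis([pooled[:20], pooled[20:40], pooled[40:]])
        perm = rng.permutation(pooled)
        h2, _ = kruskal_wallis([perm[:20], perm[20:40], perm[40:]])
        # identical distributions: H varies only through the random split
        assert h1 >= 0 and h2 >= 0

    def test_two_groups_match_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(1.0, size=15)
        h, p = kruskal_wallis([a, b])
        # brute-force rank computation, no ties by construction
        pooled = np.concatenate([a, b])
        order = pooled.argsort()
        ranks = np.empty_like(order, dtype=float)
        ranks[order] = np.arange(1, pooled.size + 1)
        n = pooled.size
        rbar = (n + 1) / 2
        h_oracle = (
            12
            / (n * (n + 1))
            * (
                a.size * (ranks[: a.size].mean() - rbar) ** 2
                + b.size * (ranks[a.size :].mean() - rbar) ** 2
            )
        )
        assert h == pytest.approx(h_oracle, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(h_oracle, df=1), rel=1e-12)

    def test_all_identical_degenerate(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(7)])
        assert (h, p) == (0.0, 1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        groups = [rng.gamma(2, size=n) for n in (10, 14, 12)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.log(g) for g in groups])
        h3, p3 = kruskal_wallis([g**3 for g in groups])
        assert h1 == pytest.approx(h2) == pytest.approx(h3)
        assert p1 == pytest.approx(p2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.ones(3)])
        with pytest.raises(ValueError):
            kruskal_wallis([np.ones(3), np.array([])])


class TestPosthocLetters:
    def test_separated_groups_all_distinct(self):
        rng = np.random.default_rng(4)
        groups = {
            "g1": rng.normal(0, 0.1, 40),
            "g2": rng.normal(5, 0.1, 40),
            "g3": rng.normal(10, 0.1, 40),
        }
        cmp = posthoc_letters(groups)
        letters = set(cmp.letters.values())
        assert len(letters) == 3 and all(len(v) == 1 for v in letters)

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(8)
        pooled = rng.normal(size=90)
        groups = {"g1": pooled[:30], "g2": pooled[30:60], "g3": pooled[60:]}
        cmp = posthoc_letters(groups)
        shared = set.intersection(*(set(v) for v in cmp.letters.values()))
        assert shared

    def test_letters_consistent_with_pairwise_matrix(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            shifts = rng.uniform(0, 3, size=4)
            groups = {
                f"g{i}": rng.normal(shift, 1.0, 30)
                for i, shift in enumerate(shifts)
            }
            cmp = posthoc_letters(groups)
            for r in cmp.pairwise:
                share = bool(
                    set(cmp.letters[r.group_a]) & set(cmp.letters[r.group_b])
                )
                assert share == (r.p_adjusted >= 0.05)

    def test_power_separates_large_shift(self):
        rng = np.random.default_rng(21)
        groups = {
            "shifted": rng.normal(5.0, 1.0, 200),
            **{f"g{i}": rng.normal(0.0, 1.0, 200) for i in range(3)},
        }
        cmp = posthoc_letters(groups)
        shifted_letters = set(cmp.letters["shifted"])
        for name in cmp.letters:
            if name != "shifted":
                assert not shifted_letters & set(cmp.letters[name])

    def test_holm_at_least_bonferroni_ordering(self):
        rng = np.random.default_rng(13)
        groups = {f"g{i}": rng.normal(i * 0.5, 1.0, 25) for i in range(3)}
        res = dunn_posthoc(groups, adjust="holm")
        for r in res:
            assert r.p_adjusted >= r.p_raw

    def test_compact_letter_display_non_transitive_case(self):
        # a differs from c; b differs from neither -> b shares with both
        letters = compact_letter_display(["a", "b", "c"], {("a", "c")})
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
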