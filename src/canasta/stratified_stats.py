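"""Sampling-design utilities and nonparametric group comparisons.

Covers the survey side (finite-population sample size, stratified
without-replacement selection) and the analysis side (median/IQR summaries,
Kruskal–Wallis with tie correction, all-pairs Dunn post-hoc z tests on mean
ranks with Holm adjustment, and a compact letter display in which groups
sharing no letter differ at the chosen significance level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class SamplingDesign:
    """Finite-population proportion design.

    ``expected_p`` defaults to 0.5 (maximum variance); ``margin`` is the
    absolute precision d; ``loss_fraction`` inflates the net size to cover
    anticipated losses (registries too corrupted to analyse).
    """

    population_size: int
    expected_p: float = 0.5
    confidence: float = 0.95
    margin: float = 0.05
    loss_fraction: float = 0.0
    stratum_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 < self.expected_p < 1:
            raise ValueError("expected_p must be in (0, 1)")
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")
        if not 0 <= self.loss_fraction < 1:
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.stratum_sizes and sum(self.stratum_sizes.values()) != self.population_size:
            raise ValueError("stratum sizes must sum to population_size")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_size(design: SamplingDesign) -> tuple[int, int]:
    """(net_n, gross_n) for a proportion under finite-population correction.

    ``n0 = z^2 p (1-p) / d^2`` corrected as ``n = n0 / (1 + (n0 - 1)/N)`` and
    rounded up; the gross size adds the loss fraction, rounded half-up.  The z
    score is the two-sided normal quantile rounded to two decimals (1.96 at
    95 %).
    """
    z = round(float(stats.norm.ppf((1 + design.confidence) / 2)), 2)
    p, d, N = design.expected_p, design.margin, design.population_size
    n0 = z * z * p * (1 - p) / (d * d)
    net = math.ceil(n0 / (1 + (n0 - 1) / N))
    gross = _round_half_up(net * (1 + design.loss_fraction))
    return net, gross


def stratified_select(
    frame: dict[str, list[str]],
    allocation: dict[str, int],
    seed: int,
) -> dict[str, list[str]]:
    """Without-replacement selection within each stratum, deterministic under
    ``seed``.

    ``frame`` maps stratum -> unit ids; ``allocation`` maps stratum -> sample
    size.  Strata are processed in sorted order so the draw does not depend on
    dict insertion order.
    """
    rng = np.random.default_rng(seed)
    sample: dict[str, list[str]] = {}
    for stratum in sorted(allocation):
        units = sorted(frame.get(stratum, []))
        k = allocation[stratum]
        if k > len(units):
            raise ValueError(
                f"allocation {k} exceeds stratum {stratum!r} size {len(units)}"
            )
        idx = rng.choice(len(units), size=k, replace=False)
        sample[stratum] = [units[i] for i in sorted(idx)]
    return sample


def proportional_allocation(
    stratum_sizes: dict[str, int], n: int
) -> dict[str, int]:
    """Largest-remainder proportional allocation of ``n`` across strata."""
    N = sum(stratum_sizes.values())
    exact = {h: n * size / N for h, size in stratum_sizes.items()}
    alloc = {h: int(math.floor(v)) for h, v in exact.items()}
    short = n - sum(alloc.values())
    for h in sorted(exact, key=lambda h: (-(exact[h] - alloc[h]), h))[:short]:
        alloc[h] += 1
    return alloc


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and chi-square p (k−1 df).

    All-identical data is the degenerate no-information case: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    h: float
    p: float
    pairwise: list[PairwiseResult]
    letters: dict[str, str]


def dunn_posthoc(
    groups: dict[str, np.ndarray], adjust: str = "holm"
) -> list[PairwiseResult]:
    """All-pairs Dunn z tests on mean ranks with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups.  Two-sided normal
    p values, Holm (default) or Bonferroni adjusted.
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = {}, {}
    pos = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = ranks[pos : pos + arr.size].mean()
        sizes[name] = arr.size
        pos += arr.size

    results = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = math.sqrt(variance_base * (1 / sizes[a] + 1 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p_raw = 2 * stats.norm.sf(abs(z))
            results.append(PairwiseResult(a, b, z, p_raw, p_raw))

    m = len(results)
    if adjust == "holm":
        order = sorted(range(m), key=lambda k: results[k].p_raw)
        running = 0.0
        for rank, k in enumerate(order):
            adj = min(1.0, (m - rank) * results[k].p_raw)
            running = max(running, adj)
            results[k].p_adjusted = running
    elif adjust == "bonferroni":
        for r in results:
            r.p_adjusted = min(1.0, m * r.p_raw)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def compact_letter_display(
    names: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Letters such that two groups share a letter iff they are not in
    ``significant_pairs``.

    Insert-and-absorb: start from one class holding every group; each
    significant pair splits any class containing both; duplicate or subsumed
    classes are then absorbed.  Letter order follows first appearance in
    ``names``.
    """
    classes: list[set[str]] = [set(names)]
    for a, b in sorted(significant_pairs):
        next_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                next_classes.append(cls - {a})
                next_classes.append(cls - {b})
            else:
                next_classes.append(cls)
        # absorb: drop classes contained in (or equal to) an earlier/larger one
        classes = []
        for cls in next_classes:
            if not any(cls <= other for other in classes) and not any(
                cls < other for other in next_classes
            ):
                classes.append(cls)
    classes.sort(key=lambda cls: min(names.index(n) for n in cls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for letter, cls in zip(alphabet, classes):
        for n in names:
            if n in cls:
                letters[n] += letter
    return letters


def posthoc_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05, adjust: str = "holm"
) -> GroupComparison:
    """Kruskal–Wallis plus Dunn post-hoc pairs and a compact letter display."""
    names = sorted(groups)
    h, p = kruskal_wallis([groups[n] for n in names])
    pairwise = dunn_posthoc(groups, adjust=adjust)
    significant = {
        (r.group_a, r.group_b) for r in pairwise if r.p_adjusted < alpha
    }
    letters = compact_letter_display(names, significant)
    return GroupComparison(h=h, p=p, pairwise=pairwise, letters=letters)
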