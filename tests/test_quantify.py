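"""Counting, RPKM, rank-sum test, DEG calling and enrichment."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from txarch.io_formats import CoverageTrack, GeneModel
from txarch.quantify import (
    benjamini_hochberg,
    call_degs,
    count_reads,
    enrich,
    rpkm,
    wilcoxon_rank_sum,
)


def _track(depth, strand="+", total=10**6, read_length=100):
    return CoverageTrack("lib", "16h", 1, strand, np.asarray(depth), total, read_length)


class TestCountReads:
    def test_uniform_depth_closed_form(self):
        genes = [GeneModel("g1", "+", 101, 400)]
        depth = np.zeros(600, dtype=int)
        depth[100:400] = 10
        assert count_reads(_track(depth), genes) == {"g1": 30}  # 3000 / 100

    def test_zero_track_gives_zero_counts(self):
        genes = [GeneModel("g1", "+", 1, 100), GeneModel("g2", "+", 200, 300)]
        assert count_reads(_track(np.zeros(400, dtype=int)), genes) == {"g1": 0, "g2": 0}

    def test_matches_naive_per_base_summation(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 50, size=2000)
        genes = [
            GeneModel(f"g{i}", "+", s, s + ln - 1)
            for i, (s, ln) in enumerate(zip(rng.integers(1, 1500, 20), rng.integers(50, 400, 20)))
        ]
        got = count_reads(_track(depth), genes)
        for g in genes:
            naive = sum(int(depth[p - 1]) for p in range(g.start, g.end + 1))
            assert got[g.gene_id] == math.floor(naive / 100 + 0.5)

    def test_gene_beyond_genome_is_error(self):
        with pytest.raises(ValueError, match="beyond"):
            count_reads(_track(np.zeros(100, dtype=int)), [GeneModel("g", "+", 50, 150)])


class TestRpkm:
    def test_closed_form(self):
        genes = [GeneModel("g", "+", 1, 1000)]
        assert rpkm({"g": 10}, genes, 10**6) == {"g": pytest.approx(10.0)}

    def test_zero_count_zero_rpkm(self):
        genes = [GeneModel("g", "+", 1, 1000)]
        assert rpkm({"g": 0}, genes, 10**6)["g"] == 0.0

    def test_invariant_to_uniform_scaling(self):
        genes = [GeneModel("g", "+", 1, 777), GeneModel("h", "+", 800, 1200)]
        base = rpkm({"g": 10, "h": 33}, genes, 5 * 10**5)
        scaled = rpkm({"g": 70, "h": 231}, genes, 35 * 10**5)
        for k in base:
            assert scaled[k] == pytest.approx(base[k])


class TestWilcoxon:
    def test_fully_separated_samples_exact_p(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of the C(6,3)=20 labelings as extreme

    def test_identical_samples_null_p(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_and_approximation(self):
        """Exact path equals an independent enumeration; the normal
        approximation stays within 0.02 on tie-free n=6 vs 6 samples."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            pooled = rng.permutation(np.arange(12, dtype=float) + rng.uniform(0, 0.4, 12))
            a, b = pooled[:6], pooled[6:]
            u, p = wilcoxon_rank_sum(a, b)
            # independent oracle: enumerate all C(12,6) labelings
            ranks = stats.rankdata(np.concatenate([a, b]))
            m = 36
            key = min(u, m - u)
            hits = total = 0
            for comb in combinations(range(12), 6):
                u_star = ranks[list(comb)].sum() - 21
                if min(u_star, m - u_star) <= key + 1e-12:
                    hits += 1
                total += 1
            assert p == pytest.approx(hits / total)
            approx = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(p - approx) <= 0.02


class TestDegCalling:
    def test_null_case_is_not_deg(self):
        recs = call_degs({"g": 100}, {"g": 100}, 10**6, 10**6)
        assert recs[0].log2fc == 0.0 and not recs[0].is_deg

    def test_swap_negates_fold_change_and_preserves_p(self):
        rng = np.random.default_rng(2)
        ca = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 40))}
        cb = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 40))}
        fwd = call_degs(ca, cb, 10**6, 2 * 10**6)
        rev = call_degs(cb, ca, 2 * 10**6, 10**6)
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc)
            assert f.p_value == pytest.approx(r.p_value, abs=1e-12)

    def test_four_fold_change_is_called(self):
        universe = {f"g{i}": 100 for i in range(50)}
        ca = dict(universe, g0=100)
        cb = dict(universe, g0=400)
        recs = {r.gene_id: r for r in call_degs(ca, cb, 10**6, 10**6)}
        assert recs["g0"].log2fc == pytest.approx(2.0, abs=0.01)
        assert recs["g0"].p_value < 1e-15
        assert recs["g0"].is_deg

    def test_stable_under_gene_order_and_uniform_scaling(self):
        """Calls do not depend on gene ordering; fold changes of expressed
        genes survive scaling both libraries by the same integer factor
        (an exact count test only gains power, so calls are preserved)."""
        rng = np.random.default_rng(3)
        ca = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 300, 30))}
        cb = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 300, 30))}
        base = call_degs(ca, cb, 10**6, 10**6)
        reordered = call_degs(
            dict(reversed(list(ca.items()))), dict(reversed(list(cb.items()))), 10**6, 10**6
        )
        assert base == reordered
        k = 3
        scaled = call_degs(
            {g: k * c for g, c in ca.items()},
            {g: k * c for g, c in cb.items()},
            k * 10**6,
            k * 10**6,
        )
        for x, y in zip(base, scaled):
            if x.is_deg:
                assert y.is_deg
            if ca[x.gene_id] > 0 and cb[x.gene_id] > 0:
                assert x.log2fc == pytest.approx(y.log2fc, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_degs({"g": -1}, {"g": 2}, 10, 10)


class TestEnrichment:
    def test_rich_factor_definition(self):
        deg = {f"d{i}" for i in range(5)}
        cat = {f"d{i}" for i in range(3)} | {f"x{i}" for i in range(7)}
        background = deg | cat | {f"y{i}" for i in range(20)}
        recs = enrich(deg, background, {g: {"C"} for g in cat})
        assert recs[0].rich_factor == pytest.approx(0.3)  # 3 DEGs / 10 category genes
        assert recs[0].n_deg_in_cat == 3 and recs[0].n_cat_in_background == 10

    def test_category_equal_to_deg_set_is_most_enriched(self):
        deg = {"a", "b", "c"}
        background = deg | {f"z{i}" for i in range(40)}
        cat_map = {g: ({"broad", "hit"} if g in deg else {"broad"}) for g in background}
        recs = {r.category_id: r for r in enrich(deg, background, cat_map)}
        assert recs["hit"].rich_factor == 1.0
        assert recs["hit"].p_value == min(r.p_value for r in recs.values())

    def test_hypergeometric_p_matches_exhaustive_enumeration(self):
        """Tail probability equals counting over all draws from a 12-gene pool."""
        background = [f"g{i}" for i in range(12)]
        cat = set(background[:5])
        n_deg = 4
        deg = set(background[2:6])  # overlap k = 3
        recs = enrich(deg, set(background), {g: {"C"} for g in cat})
        k_obs = len(deg & cat)
        hits = total = 0
        for draw in combinations(background, n_deg):
            total += 1
            if len(set(draw) & cat) >= k_obs:
                hits += 1
        assert recs[0].p_value == pytest.approx(hits / total)

    def test_deg_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich({"a"}, {"b"}, {})


def test_benjamini_hochberg_q_monotone_in_rank_and_bounded():
    rng = np.random.default_rng(4)
    p = rng.uniform(0, 1, 100)
    q = benjamini_hochberg(p)
    assert ((q >= 0) & (q <= 1)).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
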