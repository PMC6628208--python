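"""Hypergeometric machinery, threshold classification and the report."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from netweaver import (
    EnrichmentCounts,
    ExpressionSpec,
    OverlapSpec,
    classify_high_expression,
    co_target_partition,
    enrichment_report,
    generate_datasets,
    generate_expression_table,
    hypergeom_point,
    hypergeom_upper_tail,
)
from netweaver import Dataset, LocalTableBackend, build_wheel, merge_networks
from conftest import ORGANISM


def exact_point(x, m, n, k):
    """Big-integer rational oracle for the point mass."""
    return Fraction(math.comb(m, x) * math.comb(n, k - x), math.comb(m + n, k))


class TestClassifyHighExpression:
    def test_boundary_value_included(self):
        cls = classify_high_expression({"g1": 60, "g2": 10, "g3": 50}, 50)
        assert cls.high_set == {"g1", "g3"}

    def test_all_below(self):
        assert classify_high_expression({"g1": 1.0}, 50).high_set == frozenset()

    def test_threshold_zero_takes_all(self):
        cls = classify_high_expression({"g1": 0.0, "g2": 5.0}, 0)
        assert cls.high_set == {"g1", "g2"}

    def test_negative_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_high_expression({"g1": -1.0})
        with pytest.raises(ValueError):
            classify_high_expression({"g1": float("nan")})


class TestHypergeomPoint:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((2, 3, 2, 3), 0.6),   # C(3,2)C(2,1)/C(5,3) = 6/10
            ((0, 0, 10, 5), 1.0),  # no successes available: x=0 is certain
            ((3, 3, 2, 3), 0.1),
        ],
    )
    def test_small_exact_cases(self, counts, expected):
        assert hypergeom_point(EnrichmentCounts(*counts)) == pytest.approx(expected, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentCounts(4, 3, 2, 3)  # x > m
        with pytest.raises(ValueError):
            EnrichmentCounts(0, 3, 2, 6)  # k > m + n
        with pytest.raises(ValueError):
            EnrichmentCounts(0, 5, 2, 4)  # x below forced minimum k - n

    @given(
        st.integers(0, 400), st.integers(0, 400), st.integers(0, 400), st.integers(0, 400)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_rational_oracle(self, x, m, n, k):
        k = min(k, m + n)
        lo, hi = max(0, k - n), min(k, m)
        if lo > hi:
            return
        x = lo + x % (hi - lo + 1)
        p = hypergeom_point(EnrichmentCounts(x, m, n, k))
        expected = float(exact_point(x, m, n, k))
        assert p == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_at_study_scale(self):
        # independent library route at genome-sized counts
        p = hypergeom_point(EnrichmentCounts(550, 1251, 14431, 3692))
        assert p == pytest.approx(sps.hypergeom.pmf(550, 15682, 1251, 3692), rel=1e-9)

    @given(st.integers(1, 10_000), st.integers(1, 10_000), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_normalization_over_support(self, m, n, k):
        k = min(k, m + n)
        xs = np.arange(max(0, k - n), min(k, m) + 1)
        total = float(np.sum(hypergeom_point(x=xs, m=m, n=n, k=k)))
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=150, deadline=None)
    def test_duality_swap(self, x, m, n, k):
        """point(x; m, n, k) = point(x; k, m+n-k, m): drawing the sample and
        drawing the successes are the same experiment."""
        k = min(k, m + n)
        lo, hi = max(0, k - n), min(k, m)
        if lo > hi:
            return
        x = lo + x % (hi - lo + 1)
        a = hypergeom_point(EnrichmentCounts(x, m, n, k))
        b = hypergeom_point(EnrichmentCounts(x, k, m + n - k, m))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-300)


class TestHypergeomUpperTail:
    def test_full_support_is_one(self):
        assert hypergeom_upper_tail(EnrichmentCounts(0, 3, 3, 3)) == pytest.approx(1.0)

    def test_two_term_tail(self):
        # P(2) + P(3) = 0.6 + 0.1
        assert hypergeom_upper_tail(EnrichmentCounts(2, 3, 2, 3)) == pytest.approx(0.7)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_tail_dominates_point(self, x, m, n, k):
        k = min(k, m + n)
        lo, hi = max(0, k - n), min(k, m)
        if lo > hi:
            return
        x = lo + x % (hi - lo + 1)
        c = EnrichmentCounts(x, m, n, k)
        assert hypergeom_upper_tail(c) >= hypergeom_point(c) - 1e-15


def small_study(seed, planted_rate):
    """Tiny end-to-end study: 2 cores, planted shared block, expression."""
    ospec = OverlapSpec(
        n_cores=2, per_core_sizes=(60, 80), pairwise_overlaps={(0, 1): 20},
        full_overlap=0, universe_size=400, seed=seed,
    )
    datasets, truth = generate_datasets(ospec)
    backend = LocalTableBackend(
        ORGANISM,
        [(g, g, g, "") for g in truth.universe]
        + [(s, p, s, "") for p, s in truth.core_records],
    )
    net = merge_networks([build_wheel(d, backend) for d in datasets])
    part = co_target_partition(net)
    shared_block = truth.blocks[frozenset(p for p, _ in truth.core_records)]
    espec = ExpressionSpec(high_fraction_planted=planted_rate, seed=seed + 500)
    table, high = generate_expression_table(truth.universe, espec, shared_block)
    cls = classify_high_expression({g: float(v) for g, v in table.rows})
    return net, part, cls, len(high), len(truth.universe) - len(high)


class TestEnrichmentReport:
    def test_row_layout_and_counts(self, identity_backend):
        net = merge_networks([
            build_wheel(Dataset("dA", ORGANISM, "A", "DamID", ("t1", "t2")), identity_backend),
            build_wheel(Dataset("dB", ORGANISM, "B", "DamID", ("t2", "t3")), identity_backend),
        ])
        part = co_target_partition(net)
        cls = classify_high_expression({"t1": 60.0, "t2": 80.0, "t3": 1.0})
        report = enrichment_report(net, part, cls, genome_m=10, genome_n=90)
        assert list(report["subset"]) == ["A wheel", "B wheel", "A+B co-targets"]
        wheel_a = report.iloc[0]
        assert (wheel_a.x, wheel_a.k, wheel_a.m, wheel_a.n) == (2, 2, 10, 90)
        # co-target background is the network itself (3 targets, 2 high)
        block = report.iloc[2]
        assert (block.x, block.k, block.m, block.n) == (1, 1, 2, 1)

    def test_exhaustive_draw_has_probability_one(self, identity_backend):
        net = build_wheel(Dataset("dA", ORGANISM, "A", "DamID", ("t1", "t2")), identity_backend)
        part = co_target_partition(net)
        cls = classify_high_expression({"t1": 60.0, "t2": 70.0})
        report = enrichment_report(net, part, cls, genome_m=2, genome_n=0)
        assert report.iloc[0].p == pytest.approx(1.0)

    def test_point_p_decreases_with_planted_enrichment(self):
        """Median over seeds: stronger planted enrichment, smaller point p."""
        medians = []
        for rate in (0.08, 0.6):
            ps = []
            for seed in range(25):
                net, part, cls, m, n = small_study(seed, rate)
                report = enrichment_report(net, part, cls, m, n)
                ps.append(report.iloc[-1].p)  # the 2-core shared block
            medians.append(float(np.median(ps)))
        assert medians[1] < medians[0]

    def test_null_subset_not_extreme(self):
        """A shared block drawn at the background rate sits near the mode."""
        ps = []
        for seed in range(25):
            net, part, cls, m, n = small_study(seed, planted_rate=0.08)
            report = enrichment_report(net, part, cls, m, n)
            ps.append(report.iloc[-1].p)
        assert float(np.median(ps)) > 0.01

    def test_tail_flag(self, identity_backend):
        net = build_wheel(Dataset("dA", ORGANISM, "A", "DamID", ("t1", "t2")), identity_backend)
        part = co_target_partition(net)
        cls = classify_high_expression({"t1": 60.0, "t2": 0.0})
        point = enrichment_report(net, part, cls, 5, 95).iloc[0].p
        tail = enrichment_report(net, part, cls, 5, 95, tail=True).iloc[0].p
        assert tail >= point
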