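"""Deamination-model estimators: filters, MLEs, shrinkage, joint FTO fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import xlogy

from etamseq import (
    adjust_methylation,
    apparent_methylation,
    count_sites,
    estimate_conversion_rate,
    estimate_fto_efficiency,
    filter_reads,
    joint_fit_fto,
    raw_accessibility,
    shrink_accessibility,
    simulate_probes,
)
from etamseq.model import (
    AccessibilityEstimate,
    EstimationError,
    GenomicSite,
    ParameterError,
    ProbeObservation,
    SampleTable,
    SiteCount,
)

from conftest import make_read


class TestFilterReads:
    def test_majority_unconverted_removed(self):
        bad = make_read(positions=range(0, 20, 2), observed=["A"] * 6 + ["G"] * 4)
        boundary = make_read(positions=range(0, 20, 2), observed=["A"] * 5 + ["G"] * 5)
        empty = make_read(positions=(), observed=())
        kept = filter_reads([bad, boundary, empty])
        assert bad not in kept  # 0.6 > 0.5
        assert boundary in kept  # 0.5 is not > 0.5
        assert empty in kept  # 0/0 -> kept

    def test_threshold_validated(self):
        with pytest.raises(ParameterError):
            filter_reads([], max_unconverted_fraction=1.2)

    @given(st.integers(min_value=0, max_value=12), st.integers(min_value=0, max_value=12))
    @settings(deadline=None)
    def test_removal_rule_is_exact_fraction(self, n_a, n_g):
        obs = ["A"] * n_a + ["G"] * n_g
        read = make_read(positions=range(len(obs)), observed=obs)
        kept = filter_reads([read])
        if not obs:
            assert kept
        else:
            assert bool(kept) == (n_a / len(obs) <= 0.5)


class TestCountSites:
    def test_simple_tallies(self):
        reads = [
            make_read(read_id=f"r{i}", positions=(10,), observed=(b,))
            for i, b in enumerate(["G", "G", "G"])
        ]
        table = count_sites(reads)
        [sc] = list(table)
        assert (sc.a_count, sc.g_count) == (0, 3)

    def test_mixed_bases_and_other(self):
        reads = [
            make_read(read_id=f"r{i}", positions=(10,), observed=(b,))
            for i, b in enumerate(["A", "A", "G", "C"])
        ]
        [sc] = list(count_sites(reads))
        assert (sc.a_count, sc.g_count, sc.other_count) == (2, 1, 1)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(8)
        reads = []
        expected = {}
        for i in range(100):
            positions = sorted(rng.choice(50, size=rng.integers(1, 6), replace=False))
            observed = [str(rng.choice(["A", "G", "C"])) for _ in positions]
            reads.append(make_read(read_id=f"r{i}", positions=positions, observed=observed))
            for p, b in zip(positions, observed):
                counts = expected.setdefault(p, [0, 0, 0])
                counts["AG".index(b) if b in "AG" else 2] += 1
        table = count_sites(reads)
        assert len(table) == len(expected)
        for sc in table:
            assert [sc.a_count, sc.g_count, sc.other_count] == expected[sc.site.pos]


class TestConversionRate:
    def _table(self, counts):
        t = SampleTable(label="x", role="ivt")
        for i, (a, g) in enumerate(counts):
            t.add(SiteCount(GenomicSite("c", i * 10), a, g))
        return t

    def test_pooled_ratio(self):
        assert estimate_conversion_rate(self._table([(1, 99), (3, 97)])) == pytest.approx(0.98)

    def test_extremes(self):
        assert estimate_conversion_rate(self._table([(0, 50), (0, 30)])) == 1.0
        assert estimate_conversion_rate(self._table([(50, 0), (30, 0)])) == 0.0

    def test_min_coverage_and_error(self):
        table = self._table([(1, 5)])  # coverage 6 < 20
        with pytest.raises(EstimationError):
            estimate_conversion_rate(table)

    def test_trimming_discards_methylated_outliers(self):
        counts = [(1, 99)] * 18 + [(95, 5), (96, 4)]  # two highly methylated sites
        trimmed = estimate_conversion_rate(self._table(counts), trim=0.1)
        untrimmed = estimate_conversion_rate(self._table(counts))
        assert trimmed > untrimmed
        assert trimmed == pytest.approx(0.99, abs=1e-9)


class TestApparentMethylation:
    def test_clipping(self):
        assert apparent_methylation(0, 100, 0.99) == 0.0
        assert apparent_methylation(100, 0, 1.0) == 1.0

    def test_against_grid_likelihood(self):
        # pi = m + (1 - m)(1 - c); grid-search the binomial log-likelihood
        a, g, c = 261, 739, 0.9831
        m_grid = np.arange(0, 1 + 1e-9, 1e-5)
        pi = m_grid + (1 - m_grid) * (1 - c)
        ll = xlogy(a, pi) + xlogy(g, 1 - pi)
        assert apparent_methylation(a, g, c) == pytest.approx(m_grid[np.argmax(ll)], abs=1e-4)

    def test_errors(self):
        with pytest.raises(ParameterError):
            apparent_methylation(1, 1, 0.0)
        with pytest.raises(EstimationError):
            apparent_methylation(0, 0, 0.9)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=1, max_value=500),
        st.floats(min_value=0.5, max_value=1.0),
    )
    @settings(deadline=None)
    def test_monotone_in_a_at_fixed_depth(self, a, n_extra, c):
        n = a + n_extra
        m_lo = apparent_methylation(a, n - a, c)
        m_hi = apparent_methylation(a + 1, n - a - 1, c) if a + 1 <= n else 1.0
        assert m_hi >= m_lo - 1e-12


class TestAccessibility:
    def test_raw_values(self):
        assert raw_accessibility(0, 100, 0.99) == 1.0  # clipped from 1.0101
        assert raw_accessibility(15, 85, 0.9) == pytest.approx(0.85 / 0.9)
        assert raw_accessibility(10, 0, 0.99) == 0.0

    def test_adjustment_identities(self):
        assert adjust_methylation(0.45, 0.9) == (pytest.approx(0.5), pytest.approx(0.45))
        true_m, exposed = adjust_methylation(0.8, 0.5)
        assert true_m == 1.0 and exposed == 0.5
        assert adjust_methylation(0.3, 0.0) == (None, 0.0)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0.01, max_value=1))
    @settings(deadline=None)
    def test_exposed_is_min_of_apparent_and_accessibility(self, apparent, s):
        _, exposed = adjust_methylation(apparent, s)
        assert exposed == pytest.approx(min(apparent, s), abs=1e-12)


class TestShrinkAccessibility:
    @staticmethod
    def _estimates(a, g, c):
        return [
            AccessibilityEstimate(
                GenomicSite("t", i),
                raw_s=raw_accessibility(int(ai), int(gi), c),
                control_counts=(int(ai), int(gi)),
            )
            for i, (ai, gi) in enumerate(zip(a, g))
        ]

    def test_constant_response_unchanged(self):
        # every site has the same accessibility ratio 0.95 at varying coverage
        a = np.array([5, 10, 15, 20, 25]) ; g = 19 * a  # g/(a+g) = 0.95
        ests = self._estimates(a, g, c=1.0)
        with pytest.warns(UserWarning):
            shrunk = shrink_accessibility(ests, c_control=1.0, seed=0)
        assert all(e.shrunken_s == pytest.approx(0.95, abs=1e-9) for e in shrunk)

    def test_bias_reduction_on_low_coverage_accessible_sites(self):
        rng = np.random.default_rng(11)
        c = 0.99
        n = rng.integers(5, 21, size=3000)
        g = rng.binomial(n, c)  # true s = 1, unmethylated
        a = n - g
        ests = self._estimates(a, g, c)
        shrunk = shrink_accessibility(ests, c_control=c, seed=5)
        raw_err = np.mean([abs(e.raw_s - 1) for e in ests])
        shr_err = np.mean([abs(e.shrunken_s - 1) for e in shrunk])
        assert shr_err < raw_err

    def test_small_population_fallback_warns(self):
        a = np.array([1, 2, 3]); g = np.array([20, 30, 40])
        with pytest.warns(UserWarning, match="training"):
            shrunk = shrink_accessibility(self._estimates(a, g, 0.99), c_control=0.99, seed=1)
        assert len(shrunk) == 3

    def test_too_few_sites_rejected(self):
        with pytest.raises(EstimationError):
            shrink_accessibility(self._estimates([1], [9], 0.99), c_control=0.99, seed=1)


class TestFTO:
    def test_efficiency_ratio(self):
        minus = [ProbeObservation("p100", 1.0, a_count=1000, g_count=0)]
        plus = [ProbeObservation("p100", 1.0, a_count=600, g_count=400)]
        assert estimate_fto_efficiency(minus, plus, c=1.0) == pytest.approx(0.4)

    def test_efficiency_clipped_and_errors(self):
        full = [ProbeObservation("p", 1.0, a_count=500, g_count=500)]
        fuller = [ProbeObservation("p", 1.0, a_count=1000, g_count=0)]
        assert estimate_fto_efficiency(full, fuller, c=1.0) == 0.0  # m_plus > m_minus
        empty = [ProbeObservation("p", 1.0, a_count=0, g_count=1000)]
        with pytest.raises(EstimationError):
            estimate_fto_efficiency(empty, fuller, c=1.0)

    def test_joint_fit_closed_form_case(self):
        minus = SiteCount(GenomicSite("x", 10), 50, 50)
        plus = SiteCount(GenomicSite("x", 10), 1, 99)
        fit = joint_fit_fto(minus, plus, 1.0, 1.0, e=1.0)
        assert fit.s_hat == pytest.approx(0.99, abs=0.005)
        assert fit.m_hat == pytest.approx(0.4949, abs=0.005)

    def test_fully_converted_pair_gives_zero_methylation(self):
        minus = SiteCount(GenomicSite("x", 10), 0, 200)
        plus = SiteCount(GenomicSite("x", 10), 0, 200)
        fit = joint_fit_fto(minus, plus, 1.0, 1.0, e=1.0)
        assert fit.m_hat == 0.0 and fit.s_hat == 1.0

    def test_zero_efficiency_unidentifiable(self):
        sc = SiteCount(GenomicSite("x", 10), 10, 90)
        with pytest.raises(EstimationError):
            joint_fit_fto(sc, sc, 0.99, 0.99, e=0.0)

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(17)
        grid = np.linspace(0, 1, 201)
        for _ in range(20):
            m_true, s_true = rng.random(), rng.uniform(0.3, 1)
            e = rng.uniform(0.5, 1)
            cm, cp = rng.uniform(0.95, 1), rng.uniform(0.95, 1)
            n1, n2 = int(rng.integers(20, 200)), int(rng.integers(20, 200))
            a1 = int(rng.binomial(n1, 1 - cm * s_true * (1 - m_true)))
            a2 = int(rng.binomial(n2, 1 - cp * s_true * (1 - m_true * (1 - e))))
            fit = joint_fit_fto(
                SiteCount(GenomicSite("x", 10), a1, n1 - a1),
                SiteCount(GenomicSite("x", 10), a2, n2 - a2),
                cm, cp, e,
            )
            M, S = np.meshgrid(grid, grid, indexing="ij")
            pm = 1 - cm * S * (1 - M)
            pp = 1 - cp * S * (1 - M * (1 - e))
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = (
                    xlogy(a1, pm) + xlogy(n1 - a1, 1 - pm)
                    + xlogy(a2, pp) + xlogy(n2 - a2, 1 - pp)
                )
            i, _ = np.unravel_index(np.argmax(np.nan_to_num(ll, nan=-np.inf)), ll.shape)
            assert abs(fit.m_hat - grid[i]) <= 0.01

    def test_e1_converted_plus_reduces_to_ivt_path(self):
        minus = SiteCount(GenomicSite("x", 10), 45, 55)
        plus = SiteCount(GenomicSite("x", 10), 0, 100)
        fit = joint_fit_fto(minus, plus, 0.99, 0.99, e=1.0)
        s_ivt = raw_accessibility(0, 100, 0.99)
        m_ivt, _ = adjust_methylation(apparent_methylation(45, 55, 0.99), s_ivt)
        assert fit.s_hat == pytest.approx(s_ivt, abs=0.01)
        assert fit.m_hat == pytest.approx(m_ivt, abs=0.01)
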