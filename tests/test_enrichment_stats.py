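"""Enrichment statistics: background model, chi-square variants, exact test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gsoverlap import (
    BackgroundModel,
    OverlapResult,
    assess_enrichment,
    background_fraction,
    bonferroni_alpha,
    chisq_2x2,
    chisq_gof,
    expected_overlap,
    fisher_exact,
    format_p,
    round_percent,
)

IHR_F = 1629 / 18000


def brute_force_fisher(O: int, n: int, R: int, G: int) -> Fraction:
    """Exact two-sided hypergeometric p by rational enumeration.

    Independent oracle: sums exact table probabilities
    C(R,k)·C(G-R,n-k)/C(G,n) over every attainable k whose probability
    does not exceed that of the observed table.
    """
    denom = math.comb(G, n)
    prob = {
        k: Fraction(math.comb(R, k) * math.comb(G - R, n - k), denom)
        for k in range(max(0, n + R - G), min(n, R) + 1)
    }
    p_obs = prob[O]
    return sum(p for p in prob.values() if p <= p_obs)


def test_background_fraction_values():
    assert background_fraction(1629, 18000) == pytest.approx(0.0905)
    assert background_fraction(2449, 18000) == pytest.approx(0.13606, abs=1e-5)
    assert background_fraction(5, 5) == 1.0


@pytest.mark.parametrize("ref,G", [(0, 18000), (-1, 18000), (100, 0), (200, 100)])
def test_background_fraction_rejects_bad_sizes(ref, G):
    with pytest.raises(ValueError):
        background_fraction(ref, G)


def test_expected_overlap():
    assert expected_overlap(458, IHR_F) == pytest.approx(41.45, abs=0.005)
    assert expected_overlap(458, 0.0) == 0.0
    assert expected_overlap(0, 0.5) == 0.0


def test_background_model_fraction_exact():
    bg = BackgroundModel(reference_size=1629, G=18000)
    assert bg.f == 1629 / 18000


class TestChisqGof:
    def test_perfect_agreement(self):
        n, f = 200, 0.25
        statistic, p = chisq_gof(int(n * f), n, f)
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_lof_subset_overlap(self):
        # 25 shared genes in a 112-gene query at the 9% background:
        # strongly significant (values frozen from hand arithmetic,
        # (O-nf)^2/nf + ((n-O)-n(1-f))^2/n(1-f) with nf = 10.136)
        statistic, p = chisq_gof(25, 112, IHR_F)
        assert statistic == pytest.approx(23.9664, abs=1e-3)
        assert p == pytest.approx(9.803e-7, rel=1e-3)

    def test_full_gwas_set_not_significant(self):
        statistic, p = chisq_gof(51, 458, IHR_F)
        assert statistic == pytest.approx(2.42, abs=0.005)
        assert p > 0.017

    @pytest.mark.parametrize("O,n,f", [(3, 40, 0.1), (25, 112, IHR_F), (0, 10, 0.3)])
    def test_matches_library_gof(self, O, n, f):
        statistic, p = chisq_gof(O, n, f)
        oracle = stats.chisquare([O, n - O], f_exp=[n * f, n * (1 - f)])
        assert statistic == pytest.approx(float(oracle.statistic))
        assert p == pytest.approx(float(oracle.pvalue))

    def test_degenerate_expectation_errors(self):
        with pytest.raises(ValueError):
            chisq_gof(0, 10, 0.0)
        with pytest.raises(ValueError):
            chisq_gof(10, 10, 1.0)
        with pytest.raises(ValueError):
            chisq_gof(11, 10, 0.5)

    @settings(derandomize=True, max_examples=60)
    @given(
        n=st.integers(20, 600),
        ref=st.integers(100, 3000),
    )
    def test_p_monotone_in_distance_from_expectation(self, n, ref):
        f = ref / 18000
        pvals = [chisq_gof(O, n, f)[1] for O in range(n + 1)]
        E = n * f
        distances = [abs(O - E) for O in range(n + 1)]
        order = np.argsort(distances)
        ordered = [pvals[i] for i in order]
        assert all(a >= b - 1e-12 for a, b in zip(ordered, ordered[1:]))


class TestChisq2x2:
    def test_independence_gives_zero(self):
        # margins chosen so O is exactly at expectation: G=100, n=20, R=10
        statistic, p = chisq_2x2(2, 20, 10, 100)
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_full_gwas_set(self):
        statistic, _ = chisq_2x2(51, 458, 1629, 18000)
        assert statistic == pytest.approx(2.483, abs=0.005)

    @pytest.mark.parametrize(
        "O,n,R,G", [(51, 458, 1629, 18000), (25, 112, 1629, 18000), (7, 40, 60, 500)]
    )
    def test_matches_library_contingency(self, O, n, R, G):
        statistic, p = chisq_2x2(O, n, R, G)
        table = [[O, n - O], [R - O, G - n - R + O]]
        oracle = stats.chi2_contingency(table, correction=False)
        assert statistic == pytest.approx(float(oracle.statistic))
        assert p == pytest.approx(float(oracle.pvalue))

    def test_continuity_correction_matches_library(self):
        statistic, _ = chisq_2x2(25, 112, 1629, 18000, correction=True)
        table = [[25, 87], [1604, 16284]]
        oracle = stats.chi2_contingency(table, correction=True)
        assert statistic == pytest.approx(float(oracle.statistic))

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            chisq_2x2(11, 10, 50, 100)  # O > n
        with pytest.raises(ValueError):
            chisq_2x2(5, 80, 30, 100)  # negative bottom-right cell

    def test_agrees_with_gof_when_cells_large(self):
        # the statistics differ by exactly the finite-population factor
        # G/(G-n), so the 10% agreement band applies in the regime the
        # method targets: a query much smaller than the universe (n < G/11)
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 50:
            G = int(rng.integers(5000, 20000))
            n = int(rng.integers(300, G // 12))
            R = int(rng.integers(1000, 4000))
            f = R / G
            expected_cells = [n * f, n * (1 - f), (G - n) * f, (G - n) * (1 - f)]
            if min(expected_cells) < 50:
                continue
            O = int(np.clip(rng.binomial(n, f) + rng.integers(-5, 6), 0, min(n, R)))
            s1, _ = chisq_gof(O, n, f)
            s2, _ = chisq_2x2(O, n, R, G)
            if s1 > 0.1:  # relative comparison meaningless at ~0
                assert abs(s1 - s2) / s1 < 0.10
            checked += 1


class TestFisherExact:
    def test_degenerate_margin_query_is_universe(self):
        assert fisher_exact(5, 10, 5, 10) == pytest.approx(1.0)

    def test_small_case_against_brute_force(self):
        p = fisher_exact(4, 4, 5, 10)
        assert p == pytest.approx(float(brute_force_fisher(4, 4, 5, 10)), abs=1e-12)

    def test_mode_gives_large_p(self):
        # symmetric case: G=20, n=10, R=10, observed at the mode O=5
        assert fisher_exact(5, 10, 10, 20) > 0.5

    @pytest.mark.parametrize(
        "O,n,R,G", [(4, 4, 5, 10), (0, 6, 8, 25), (3, 7, 9, 30), (12, 40, 50, 400)]
    )
    def test_matches_library_fisher(self, O, n, R, G):
        table = [[O, n - O], [R - O, G - n - R + O]]
        oracle = float(stats.fisher_exact(table, alternative="two-sided")[1])
        assert fisher_exact(O, n, R, G) == pytest.approx(oracle, abs=1e-9)


def test_bonferroni_alpha():
    assert bonferroni_alpha(0.05, 3) == pytest.approx(0.016667, abs=1e-5)
    assert f"{bonferroni_alpha(0.05, 3):.3f}" == "0.017"
    assert bonferroni_alpha(0.05, 1) == 0.05
    assert bonferroni_alpha(0.10, 2) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


class TestAssessEnrichment:
    BG = BackgroundModel(reference_size=1629, G=18000)

    def _overlap(self, O, n):
        return OverlapResult("Q", "R", n=n, O=O, shared=frozenset())

    def test_at_expectation_is_none(self):
        bg = BackgroundModel(reference_size=4500, G=18000)  # f = 0.25
        result = assess_enrichment(self._overlap(25, 100), bg, alpha=0.017)
        assert result.direction == "none"
        assert not result.significant

    def test_lof_subset_enriched(self):
        result = assess_enrichment(self._overlap(25, 112), self.BG, alpha=0.017)
        assert result.significant and result.direction == "enriched"
        assert result.E == pytest.approx(112 * IHR_F)
        assert result.method == "gof_1sample" and result.df == 1

    def test_depleted_overlap_never_significant(self):
        bg = BackgroundModel(reference_size=2289, G=18000)
        result = assess_enrichment(self._overlap(48, 458), bg, alpha=0.017)
        assert result.direction == "depleted"
        assert not result.significant
        # even an extreme depletion with tiny p stays non-significant
        extreme = assess_enrichment(self._overlap(0, 458), bg, alpha=0.017)
        assert extreme.p < 0.017 and not extreme.significant

    @pytest.mark.parametrize("method", ["gof_1sample", "chisq_2x2", "fisher_exact"])
    def test_methods_dispatch(self, method):
        result = assess_enrichment(
            self._overlap(25, 112), self.BG, alpha=0.017, method=method
        )
        assert result.method == method
        assert 0 < result.p <= 1
        assert result.significant  # all three agree on this clear-cut case


def test_expected_overlap_partition_additivity():
    # E is linear in n: summing E over any partition of the query equals
    # E of the whole query
    f = IHR_F
    parts = [112, 96, 46, 204]
    assert sum(expected_overlap(n, f) for n in parts) == pytest.approx(
        expected_overlap(sum(parts), f)
    )


@pytest.mark.parametrize(
    "num,den,expected",
    [(96, 458, 21), (452, 1629, 28), (270, 1112, 24), (1629, 18000, 9), (2449, 18000, 14)],
)
def test_round_percent(num, den, expected):
    assert round_percent(num, den) == expected


def test_format_p():
    assert format_p(8.4e-7) == "0.0001"
    assert format_p(0.0095) == "0.0095"
    assert format_p(1.0) == "1.0000"
    with pytest.raises(ValueError):
        format_p(0.0)
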