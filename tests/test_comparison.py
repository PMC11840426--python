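"""Pairwise contingency tests, Fisher enumeration oracle, Holm adjustment."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from owlpellets import (
    ContingencyTable,
    ValidationError,
    build_table,
    chi_squared_yates,
    choose_test,
    compare_pair,
    fisher_exact,
    holm_adjust,
    pairwise_compare,
)
from owlpellets.abundance import pool_abundance
from owlpellets.pipeline import DEFAULT_COMPARISON_TAXA
from owlpellets.taxonomy import HISTORIC_PROFILE


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by enumerating all same-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: Fraction(comb(r1, x) * comb(r2, c1 - x)) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestBuildTable:
    def test_margins(self):
        t = build_table(135, 439, 68, 427)
        assert (t.a, t.b, t.c, t.d) == (135, 304, 68, 359)
        assert t.N == 866

    def test_empty_and_saturated_cells(self):
        assert build_table(0, 10, 0, 10).N == 20
        t = build_table(5, 5, 0, 5)
        assert (t.a, t.b, t.c, t.d) == (5, 0, 0, 5)

    def test_focal_above_total_rejected(self):
        with pytest.raises(ValidationError):
            build_table(11, 10, 0, 10)


class TestYatesChiSquared:
    @pytest.mark.parametrize(
        "table,expected_chi2",
        [
            ((135, 304, 68, 359), 25.69),   # S. douglasi, Initial vs Winter
            ((68, 359, 24, 177), 1.43),     # S. douglasi, Winter vs Summer
            ((150, 277, 137, 263), 0.04),   # R. villosissimus, Winter vs Historic
            ((106, 333, 115, 86), 65.23),   # R. villosissimus, Initial vs Summer
            ((113, 326, 21, 180), 18.57),   # pooled birds, Initial vs Summer
            ((16, 423, 19, 182), 7.91),     # unidentifiable, Initial vs Summer
        ],
    )
    def test_reproduces_published_statistics(self, table, expected_chi2):
        chi2, df, p = chi_squared_yates(ContingencyTable(*table))
        assert df == 1
        assert chi2 == pytest.approx(expected_chi2, abs=0.005)

    def test_identical_proportions_clamp_to_zero(self):
        chi2, _, p = chi_squared_yates(ContingencyTable(10, 10, 10, 10))
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_closed_form(self):
        a, b, c, d = 30, 70, 45, 55
        n = a + b + c + d
        num = n * max(abs(a * d - b * c) - n / 2, 0) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        chi2, _, _ = chi_squared_yates(ContingencyTable(a, b, c, d))
        assert chi2 == pytest.approx(num / den, rel=1e-12)

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
    def test_invariant_under_row_and_column_swaps(self, a, b, c, d):
        base = chi_squared_yates(ContingencyTable(a, b, c, d))[0]
        assert chi_squared_yates(ContingencyTable(c, d, a, b))[0] == pytest.approx(base)
        assert chi_squared_yates(ContingencyTable(b, a, d, c))[0] == pytest.approx(base)

    def test_zero_margin_directs_to_fisher(self):
        with pytest.raises(ValidationError, match="[Ff]isher"):
            chi_squared_yates(ContingencyTable(0, 10, 0, 10))


class TestFisherExact:
    def test_degenerate_margins_give_one(self):
        assert fisher_exact(ContingencyTable(0, 10, 0, 10)) == 1.0
        assert fisher_exact(ContingencyTable(0, 0, 5, 5)) == 1.0

    def test_symmetric_table_gives_one(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_sparse_table_matches_enumeration(self):
        t = ContingencyTable(2, 437, 4, 197)
        assert fisher_exact(t) == pytest.approx(float(fisher_oracle(2, 437, 4, 197)), rel=1e-7)

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            ours = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            ref = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_exhaustive_against_oracle_all_small_tables(self):
        """All 2x2 tables with N <= 40 agree with the exact-rational oracle."""
        for n in range(0, 41):
            for r1 in range(0, n + 1):
                r2 = n - r1
                for c1 in range(0, n + 1):
                    lo, hi = max(0, c1 - r2), min(r1, c1)
                    if lo > hi:
                        continue
                    for a in range(lo, hi + 1):
                        b, c = r1 - a, c1 - a
                        d = r2 - c
                        ours = fisher_exact(ContingencyTable(a, b, c, d))
                        exact = float(fisher_oracle(a, b, c, d))
                        assert ours == pytest.approx(exact, rel=1e-6, abs=1e-12), (a, b, c, d)


class TestChooseTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((2, 437, 2, 425), "fisher_exact"),        # L. forresti, sparse
            ((135, 304, 68, 359), "chi_squared_yates"),
            ((5, 5, 5, 5), "chi_squared_yates"),        # expected exactly 5
            ((1, 9, 0, 10), "fisher_exact"),
        ],
    )
    def test_expected_count_rule(self, table, expected):
        assert choose_test(ContingencyTable(*table)) == expected


class TestHolm:
    @pytest.mark.parametrize(
        "raw,adjusted",
        [
            ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
            ([0.5], [0.5]),
            ([0.2, 0.9], [0.4, 0.9]),
        ],
    )
    def test_step_down_rule(self, raw, adjusted):
        assert holm_adjust(raw) == pytest.approx(adjusted)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_dominates_raw_and_capped_at_one(self, ps):
        adj = holm_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)

    def test_preserves_order_on_sorted_input(self):
        ps = sorted([0.001, 0.02, 0.3, 0.9, 0.04])
        adj = holm_adjust(ps)
        assert adj == sorted(adj)


@pytest.fixture(scope="module")
def results(toorak_vectors):
    pooled = [pool_abundance(v, HISTORIC_PROFILE) for v in toorak_vectors.values()]
    res = pairwise_compare(pooled, DEFAULT_COMPARISON_TAXA)
    return {(r.taxon, r.pair): r for r in res}


class TestPairwiseCompare:

    def test_rat_winter_vs_historic_statistic(self, results):
        r = results[("Rattus villosissimus", ("Winter", "Historic"))]
        assert r.statistic == pytest.approx(0.04, abs=0.005)
        assert r.significance == "ns"

    def test_dunnart_initial_vs_historic_highly_significant(self, results):
        r = results[("Sminthopsis douglasi", ("Initial", "Historic"))]
        assert r.statistic == pytest.approx(107.07, abs=0.005)
        assert r.significance == "****"

    def test_all_present_day_chi_squared_statistics(self, results):
        expected = {
            ("Sminthopsis douglasi", ("Initial", "Winter")): 25.69,
            ("Sminthopsis douglasi", ("Initial", "Summer")): 25.13,
            ("Sminthopsis douglasi", ("Winter", "Summer")): 1.43,
            ("Sminthopsis macroura", ("Initial", "Winter")): 0.09,
            ("Sminthopsis macroura", ("Initial", "Summer")): 0.76,
            ("Sminthopsis macroura", ("Winter", "Summer")): 0.25,
            ("Planigale spp.", ("Initial", "Winter")): 0.83,
            ("Planigale spp.", ("Initial", "Summer")): 1.61,
            ("Planigale spp.", ("Winter", "Summer")): 0.23,
            ("Rattus villosissimus", ("Initial", "Winter")): 12.02,
            ("Rattus villosissimus", ("Initial", "Summer")): 65.23,
            ("Rattus villosissimus", ("Winter", "Summer")): 26.43,
            ("Aves spp.", ("Initial", "Winter")): 1.18,
            ("Aves spp.", ("Initial", "Summer")): 18.57,
            ("Aves spp.", ("Winter", "Summer")): 26.10,
            ("unidentifiable", ("Initial", "Winter")): 1.88,
            ("unidentifiable", ("Initial", "Summer")): 7.91,
            ("unidentifiable", ("Winter", "Summer")): 2.19,
        }
        for key, chi2 in expected.items():
            r = results[key]
            assert r.test == "chi_squared_yates"
            assert r.statistic == pytest.approx(chi2, abs=0.005), key

    def test_sample_sizes_match_collection_totals(self, results):
        assert results[("Sminthopsis douglasi", ("Initial", "Winter"))].N == 866
        assert results[("Sminthopsis douglasi", ("Initial", "Historic"))].N == 839

    def test_unknown_historic_counts_are_skipped(self, results):
        assert ("Planigale spp.", ("Initial", "Historic")) not in results
        assert ("unidentifiable", ("Winter", "Historic")) not in results

    def test_sparse_taxa_use_fisher(self, results):
        r = results[("Leggadina forresti", ("Initial", "Winter"))]
        assert r.test == "fisher_exact"
        assert r.statistic is None

    def test_identical_collections_all_non_significant(self, toorak_vectors):
        v = toorak_vectors["Initial"]
        import dataclasses

        v2 = dataclasses.replace(v, collection_id="copy")
        res = pairwise_compare([v, v2], ["Sminthopsis douglasi", "Planigale spp."])
        assert all(r.p_adj == pytest.approx(1.0) and r.significance == "ns" for r in res)

    def test_adjusted_never_below_raw(self, results):
        assert all(r.p_adj >= r.p_raw - 1e-15 for r in results.values())
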