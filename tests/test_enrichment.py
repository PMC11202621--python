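"""Contingency construction, Yates chi-squared, hypergeometric
over-representation, BH adjustment, and the gene-set driver."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonemut.enrichment import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    chisq_yates,
    enrich_gene_sets,
    hypergeom_overrep,
)
from clonemut.errors import ConfigurationError, DegenerateTableError
from clonemut.synthetic_data import simulate_membership_study, simulate_null_sets


class TestBuildContingency:
    def test_margin_arithmetic(self):
        t = build_contingency(15096, 954, 420, 50)
        assert (t.a, t.b, t.c, t.d) == (50, 370, 904, 13772)

    def test_full_containment_and_disjoint(self):
        assert build_contingency(100, 10, 10, 10) == ContingencyTable(10, 0, 0, 90)
        assert build_contingency(100, 10, 10, 0) == ContingencyTable(0, 10, 10, 80)

    def test_infeasible_margins_rejected(self):
        with pytest.raises(ConfigurationError):
            build_contingency(100, 10, 10, 11)
        with pytest.raises(ConfigurationError):
            build_contingency(15, 10, 10, 0)  # d would be negative


def yates_oracle(a, b, c, d):
    """Cell-by-cell literal evaluation of the corrected statistic."""
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    total = 0.0
    for (i, j), o in (((0, 0), a), ((0, 1), b), ((1, 0), c), ((1, 1), d)):
        e = rows[i] * cols[j] / n
        diff = abs(o - e)
        total += (diff - min(0.5, diff)) ** 2 / e
    return total


class TestChisqYates:
    def test_balanced_table_statistic_zero(self):
        # observed == expected; the clamp keeps the correction from
        # manufacturing a nonzero statistic
        result = chisq_yates(ContingencyTable(10, 10, 10, 10))
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_small_table_against_oracle(self):
        result = chisq_yates(ContingencyTable(5, 5, 5, 15))
        assert result.statistic == pytest.approx(yates_oracle(5, 5, 5, 15), abs=1e-9)

    def test_thousand_random_tables_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 400, size=4)
            result = chisq_yates(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert result.statistic == pytest.approx(
                yates_oracle(int(a), int(b), int(c), int(d)), abs=1e-9
            )
            assert result.df == 1 and 0 < result.p_value <= 1

    def test_agrees_with_scipy_when_clamp_inactive(self):
        # |O-E| > 0.5 for this table, so scipy's uncapped correction and
        # the clamped formula coincide
        table = ContingencyTable(50, 370, 904, 13772)
        ours = chisq_yates(table)
        theirs = stats.chi2_contingency(table.as_array(), correction=True)
        assert ours.statistic == pytest.approx(theirs.statistic, abs=1e-9)
        assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-12)

    def test_transposition_and_double_swap_invariance(self):
        t = ContingencyTable(7, 21, 13, 59)
        transposed = ContingencyTable(7, 13, 21, 59)
        swapped = ContingencyTable(59, 13, 21, 7)
        base = chisq_yates(t).statistic
        assert chisq_yates(transposed).statistic == pytest.approx(base, abs=1e-12)
        assert chisq_yates(swapped).statistic == pytest.approx(base, abs=1e-12)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chisq_yates(ContingencyTable(0, 0, 5, 5))


def hypergeom_enumeration_oracle(n_total, n_set, n_query, n_overlap):
    """Exhaustive subset enumeration: fraction of query subsets whose
    overlap with a fixed set reaches n_overlap."""
    universe = range(n_total)
    marked = set(range(n_set))
    hits = total = 0
    for subset in itertools.combinations(universe, n_query):
        total += 1
        hits += len(marked & set(subset)) >= n_overlap
    return hits / total


class TestHypergeomOverrep:
    def test_single_extreme_outcome_closed_form(self):
        assert hypergeom_overrep(20, 5, 5, 5) == pytest.approx(
            1 / math.comb(20, 5), rel=1e-12
        )

    def test_zero_overlap_is_certain(self):
        assert hypergeom_overrep(100, 10, 10, 0) == 1.0

    def test_all_feasible_small_tables_match_enumeration(self):
        for n_total in range(1, 13):
            for n_set in range(0, n_total + 1):
                for n_query in range(0, n_total + 1):
                    hi = min(n_set, n_query)
                    lo = max(0, n_set + n_query - n_total)
                    for k in range(lo, hi + 1):
                        p = hypergeom_overrep(n_total, n_set, n_query, k)
                        oracle = hypergeom_enumeration_oracle(
                            n_total, n_set, n_query, k
                        )
                        assert p == pytest.approx(oracle, abs=1e-12)

    def test_monotone_decreasing_in_overlap(self):
        ps = [hypergeom_overrep(200, 30, 40, k) for k in range(0, 20)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_infeasible_rejected(self):
        with pytest.raises(ConfigurationError):
            hypergeom_overrep(20, 5, 5, 6)


class TestBhAdjust:
    def test_hand_stepup(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_equal_fixed_points(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([0.4, 0.4, 0.4]), 0.4)

    def test_order_preserved_and_monotone_when_sorted(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        srt = bh_adjust(np.sort(p))
        assert (np.diff(srt) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.1, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_stepup_properties_hold_for_any_input(self, p_values):
        adjusted = bh_adjust(p_values)
        assert (adjusted <= 1.0 + 1e-15).all()
        assert (adjusted >= np.asarray(p_values) - 1e-15).all()
        order = np.argsort(p_values, kind="stable")
        assert (np.diff(adjusted[order]) >= -1e-12).all()


@settings(derandomize=True, max_examples=100)
@given(
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=1, max_value=500),
)
def test_yates_statistic_nonnegative_and_symmetric(a, b, c, d):
    base = chisq_yates(ContingencyTable(a, b, c, d))
    assert base.statistic >= 0.0
    assert chisq_yates(ContingencyTable(a, c, b, d)).statistic == pytest.approx(
        base.statistic, abs=1e-9
    )


class TestEnrichGeneSets:
    def test_planted_enriched_set_ranks_first(self):
        """One set planted at odds ratio 8 among 50 uniform null sets is
        ranked first and significant at alpha 0.01."""
        background, query, listed = simulate_membership_study(7, 2000, 400, 60, 8.0)
        collection = simulate_null_sets(
            np.random.default_rng(8), background, 50, 60
        )
        collection["planted"] = set(listed)
        results = enrich_gene_sets(query, collection, background, alpha=0.01)
        assert results[0].set_name == "planted"
        assert results[0].significant
        assert results[0].adjusted_p >= results[0].p_value

    def test_disjoint_set_not_significant(self):
        background = [f"G{i}" for i in range(100)]
        results = enrich_gene_sets(
            background[:10], {"disjoint": background[50:60]}, background
        )
        assert results[0].n_overlap == 0 and not results[0].significant

    def test_duplicates_and_case_deduplicated(self):
        background = [f"G{i}" for i in range(50)]
        collection = {"s": ["g1", "G1", " g1 ", "G2"]}
        results = enrich_gene_sets(["G1", "G2"], collection, background)
        assert results[0].n_set == 2
        assert results[0].n_overlap == 2

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigurationError):
            enrich_gene_sets(["G1"], {"s": ["G1"]}, [])

    def test_null_pvalues_roughly_uniform(self):
        """Over 200 uniform null sets the raw p < 0.05 fraction sits near
        its nominal level."""
        rng = np.random.default_rng(123)
        background = [f"BG{i:05d}" for i in range(2000)]
        query = [background[i] for i in rng.choice(2000, 400, replace=False)]
        sets = simulate_null_sets(rng, background, 200, 60)
        results = enrich_gene_sets(query, sets, background, alpha=0.05)
        frac = np.mean([r.p_value < 0.05 for r in results])
        assert 0.02 <= frac <= 0.08
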