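import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from phoscoreg import (
    ConfidenceCriteria,
    CoRegulationCall,
    SimulationConfig,
    SiteKey,
    apply_confidence_filters,
    classify_coregulation,
    code_pair_states,
    coregulation_screen,
    corpus_matrix,
    fisher_exact_two_sided,
    simulate_corpus,
)
from phoscoreg.coregulation import PairStateCounts, fisher_exact_one_sided_tail

from conftest import ANCHOR, PARTNER, make_matrix
from exact_oracles import fet_two_sided_exact


class TestPairCoding:
    def test_hand_enumerated_six_condition_toy(self, toy_matrix):
        """Joint states UUDNUN vs UDDNNU: one UU, one UD, one DD, one NN, two half-calls."""
        pair = code_pair_states(toy_matrix, ANCHOR, PARTNER)
        assert (pair.uu, pair.ud, pair.dd, pair.du) == (1, 1, 1, 0)
        assert (pair.a, pair.b, pair.c, pair.d) == (1, 2, 1, 2)
        assert pair.n == 6

    def test_supporting_sets_collect_direction_events(self, toy_matrix):
        pair = code_pair_states(toy_matrix, ANCHOR, PARTNER)
        # d-events in E1 (UU) and E3 (DD); c-event in E2 (UD)
        assert pair.supporting_conditions_pos == {"E1", "E3"}
        assert pair.supporting_pmids_pos == {"P1", "P2"}
        assert pair.supporting_conditions_neg == {"E2"}
        assert pair.supporting_pmids_neg == {"P1"}

    def test_identical_partner_is_pure_positive(self):
        m = make_matrix(
            {ANCHOR: list("UUDNU"), PARTNER: list("UUDNU")},
            {f"E{i}": "P1" for i in range(5)},
        )
        pair = code_pair_states(m, ANCHOR, PARTNER)
        assert pair.c == 0 and pair.b == 0
        assert pair.d == 4  # anchor's non-N count

    def test_never_called_partner_gives_only_half_calls(self):
        m = make_matrix(
            {ANCHOR: list("UUDNU"), PARTNER: list("NNNNN")},
            {f"E{i}": "P1" for i in range(5)},
        )
        pair = code_pair_states(m, ANCHOR, PARTNER)
        assert pair.b == 4 and pair.c == 0 and pair.d == 0

    def test_self_pairing_disallowed(self, toy_matrix):
        with pytest.raises(ValueError, match="self-pairing"):
            code_pair_states(toy_matrix, ANCHOR, ANCHOR)


class TestFisherExact:
    def test_balanced_and_degenerate_tables_are_exactly_one(self):
        assert fisher_exact_two_sided(1, 1, 1, 1) == 1.0
        assert fisher_exact_two_sided(5, 0, 0, 0) == 1.0

    def test_worked_table_matches_enumeration_oracle(self):
        p = fisher_exact_two_sided(10, 2, 1, 7)
        assert p == pytest.approx(float(fet_two_sided_exact(10, 2, 1, 7)), abs=1e-12)

    @pytest.mark.parametrize(
        "table",
        [(0, 0, 0, 1), (3, 0, 0, 3), (0, 5, 5, 0), (12, 8, 11, 9), (1, 0, 0, 39),
         (7, 0, 3, 2), (2, 2, 2, 2), (0, 10, 0, 10)],
    )
    def test_matches_oracle_and_scipy_on_assorted_tables(self, table):
        a, b, c, d = table
        p = fisher_exact_two_sided(a, b, c, d)
        assert p == pytest.approx(float(fet_two_sided_exact(a, b, c, d)), abs=1e-10)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]]).pvalue, abs=1e-9)

    @settings(max_examples=300, deadline=None)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_property_sweep_against_exact_oracle(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(a, b, c, d)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(float(fet_two_sided_exact(a, b, c, d)), abs=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_relabeling_symmetry(self, table):
        """Swapping both rows and both columns leaves the p-value unchanged."""
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(a, b, c, d)
        assert fisher_exact_two_sided(d, c, b, a) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_two_sided(b, a, d, c) == pytest.approx(p, abs=1e-12)

    def test_two_sided_at_least_one_sided_tail_at_extreme_table(self):
        # the most extreme admissible table for margins (6,6)/(6,6)
        a, b, c, d = 6, 0, 0, 6
        assert fisher_exact_two_sided(a, b, c, d) >= fisher_exact_one_sided_tail(a, b, c, d)

    def test_empty_table_and_bad_cells_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_exact_two_sided(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 1, 1, 1)


def pair_with(d=0, c=0, pmids=(), conditions=()):
    uu, dd = d // 2, d - d // 2
    ud, du = c // 2, c - c // 2
    return PairStateCounts(
        anchor=ANCHOR, partner=PARTNER, uu=uu, dd=dd, ud=ud, du=du, a=5, b=5,
        supporting_pmids_pos=frozenset(pmids), supporting_conditions_pos=frozenset(conditions),
        supporting_pmids_neg=frozenset(pmids), supporting_conditions_neg=frozenset(conditions),
    )


class TestClassification:
    @pytest.mark.parametrize(
        "d,c,direction",
        [(12, 1, "positive"), (3, 3, "none"), (0, 5, "negative"),
         (1, 0, "positive"), (0, 0, "none")],
    )
    def test_dominance_direction(self, d, c, direction):
        assert classify_coregulation(pair_with(d=d, c=c)) == direction

    def test_dominance_ratio_raises_the_bar(self):
        strict = ConfidenceCriteria(dominance_ratio=3.0)
        assert classify_coregulation(pair_with(d=5, c=2), strict) == "none"
        assert classify_coregulation(pair_with(d=6, c=2), strict) == "positive"


class TestConfidenceFilters:
    def make_call(self, d, pmids, conditions, p):
        pair = pair_with(d=d, pmids=pmids, conditions=conditions)
        return CoRegulationCall(pair=pair, fet_p=p, direction="positive")

    def test_passing_pair_at_the_ten_percent_rule(self):
        call = self.make_call(
            12, ["p1", "p2", "p3"], [f"c{i}" for i in range(12)], 0.001
        )
        out = apply_confidence_filters(call, anchor_diff_frequency=103)
        assert out.passes_filters  # 12 >= 0.1 * 103
        assert all(out.filter_log.values())

    def test_too_few_studies_fails(self):
        call = self.make_call(12, ["p1", "p2"], [f"c{i}" for i in range(12)], 0.001)
        out = apply_confidence_filters(call, 103)
        assert not out.passes_filters and not out.filter_log["min_pmids"]

    def test_insignificant_p_fails_regardless_of_counts(self):
        call = self.make_call(50, ["p1", "p2", "p3"], [f"c{i}" for i in range(50)], 0.2)
        out = apply_confidence_filters(call, 103)
        assert not out.passes_filters and not out.filter_log["alpha"]

    def test_frequency_fraction_boundary(self):
        call = self.make_call(10, ["p1", "p2", "p3"], [f"c{i}" for i in range(10)], 0.001)
        assert apply_confidence_filters(call, 100).passes_filters      # 10 >= 10.0
        assert not apply_confidence_filters(call, 101).passes_filters  # 10 < 10.1


class TestScreen:
    def test_single_site_matrix_yields_no_pairs(self):
        m = make_matrix({ANCHOR: list("UDU")}, {f"E{i}": "P1" for i in range(3)})
        assert coregulation_screen(m, ANCHOR) == []

    def test_absent_anchor_is_an_error(self, toy_matrix):
        with pytest.raises(ValueError, match="anchor"):
            coregulation_screen(toy_matrix, SiteKey("ABSENT", "S", 1))

    def test_same_protein_sites_excluded_by_default(self):
        intra = SiteKey("PKN1", "S", 916)
        m = make_matrix(
            {ANCHOR: list("UDU"), intra: list("UDU"), PARTNER: list("UDU")},
            {f"E{i}": "P1" for i in range(3)},
        )
        partners = {c.pair.partner for c in coregulation_screen(m, ANCHOR)}
        assert partners == {PARTNER}
        widened = {c.pair.partner
                   for c in coregulation_screen(m, ANCHOR, include_same_protein=True)}
        assert widened == {PARTNER, intra}

    def test_planted_positive_partner_leads_the_screen(self, default_corpus, default_matrix):
        calls = coregulation_screen(default_matrix, default_corpus.anchor)
        planted = default_corpus.sites_with_role("positive_partner")[0]
        assert calls[0].pair.partner == planted
        assert calls[0].direction == "positive"
        nulls = {s for s in default_corpus.sites_with_role("null")}
        null_ps = [c.fet_p for c in calls if c.pair.partner in nulls]
        assert calls[0].fet_p < min(null_ps)

    def test_condition_conservation_for_every_pair(self, default_matrix, default_corpus):
        for call in coregulation_screen(default_matrix, default_corpus.anchor):
            assert call.pair.n == default_matrix.n_conditions

    def test_screen_is_pure_and_order_independent(self, default_corpus, default_matrix):
        anchor = default_corpus.anchor
        other = default_corpus.sites_with_role("null")[0]
        first = coregulation_screen(default_matrix, anchor)
        coregulation_screen(default_matrix, other)  # interleave another screen
        second = coregulation_screen(default_matrix, anchor)
        assert [(c.pair.partner, c.fet_p, c.direction) for c in first] == [
            (c.pair.partner, c.fet_p, c.direction) for c in second
        ]

    def test_bh_adjustment_is_off_by_default_and_monotone_when_on(self, default_corpus,
                                                                  default_matrix):
        raw = coregulation_screen(default_matrix, default_corpus.anchor)
        assert all(c.fet_p_adj is None for c in raw)
        adj = coregulation_screen(
            default_matrix, default_corpus.anchor, ConfidenceCriteria(bh_adjust=True)
        )
        assert all(c.fet_p_adj >= c.fet_p - 1e-15 for c in adj)
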