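"""The conservative Fisher test, folds, BH correction and the call logic."""

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from inoenrich.enrichment import (
    ContingencyTable,
    EmptySubnetworkError,
    bh_correct,
    build_table,
    enrichment_fold,
    modified_fisher,
    run_enrichment,
)
from inoenrich.network import AnnotatedNetwork, build_network
from inoenrich.ontology import InteractionTerm, OntologyGraph
from inoenrich.tagging import InteractionRecord


def oracle_tail(a, N, K, n, direction):
    """Exact hypergeometric tail by integer enumeration (independent oracle)."""
    xmin, xmax = max(0, n - (N - K)), min(n, K)
    if direction == "over":
        xs = range(max(a, xmin), xmax + 1)
    else:
        xs = range(xmin, min(a, xmax) + 1)
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in xs)
    return float(Fraction(num, math.comb(N, n)))


def oracle_modified(table, direction):
    a, b, A, B = table.a, table.b, table.A, table.B
    if direction == "over":
        a = max(a - 1, 0)
    else:
        a = min(a + 1, min(table.a + table.b, A))
    return oracle_tail(a, a + b + A + B, a + A, a + b, direction)


class TestModifiedFisher:
    def test_worked_table_matches_enumeration_oracle(self):
        t = ContingencyTable(30, 150, 1500, 30000)
        p = modified_fisher(t, "over")
        assert p == pytest.approx(oracle_modified(t, "over"), rel=1e-12)

    def test_zero_hits_cannot_be_overrepresented(self):
        assert modified_fisher(ContingencyTable(0, 50, 10, 90), "over") == 1.0

    def test_small_table_against_oracle_both_directions(self):
        t = ContingencyTable(3, 7, 10, 80)
        for d in ("over", "under"):
            assert modified_fisher(t, d) == pytest.approx(
                oracle_modified(t, d), rel=1e-12
            )
            assert modified_fisher(t, d, modified=False) == pytest.approx(
                oracle_tail(3, 100, 13, 10, d), rel=1e-12
            )

    @given(st.integers(0, 2_000))
    def test_random_tables_match_oracle(self, seed):
        rng = random.Random(seed)
        A = rng.randint(1, 120)
        B = rng.randint(0, 120)
        a = rng.randint(0, A)
        b = rng.randint(0, min(120, A + B - a))
        t = ContingencyTable(a, b, A, B)
        for d in ("over", "under"):
            for mod in (True, False):
                got = modified_fisher(t, d, modified=mod)
                want = (
                    oracle_modified(t, d)
                    if mod
                    else oracle_tail(a, a + b + A + B, a + A, a + b, d)
                )
                assert got == pytest.approx(want, rel=1e-10, abs=1e-300)

    def test_monotone_in_evidence_cell(self):
        # more sub-network hits (margins held by compensating b) -> smaller p
        prev = 1.1
        for a in range(0, 31):
            p = modified_fisher(ContingencyTable(a, 60 - a, 300, 5700), "over")
            assert p <= prev + 1e-15
            prev = p

    def test_minus_one_is_conservative(self):
        for (a, b, A, B) in [(1, 9, 5, 95), (5, 5, 20, 30), (30, 150, 1500, 30000)]:
            t = ContingencyTable(a, b, A, B)
            assert modified_fisher(t, "over") >= modified_fisher(
                t, "over", modified=False
            )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 5, 5, 5)
        with pytest.raises(ValueError):
            ContingencyTable(10, 0, 5, 100)  # a > A
        with pytest.raises(ValueError):
            ContingencyTable(5, 100, 10, 20)  # sub total > whole total

    def test_two_sided_at_least_one_sided(self):
        t = ContingencyTable(8, 12, 30, 170)
        one = modified_fisher(t, "over")
        two = modified_fisher(t, "over", sided="two")
        assert two >= one - 1e-15


class TestFold:
    def test_worked_example_three_point_five(self):
        assert enrichment_fold(ContingencyTable(30, 150, 1500, 30000)) == pytest.approx(3.5)

    def test_equal_proportions_unity(self):
        assert enrichment_fold(ContingencyTable(5, 45, 100, 900)) == pytest.approx(1.0)

    def test_zero_hits_zero_fold(self):
        assert enrichment_fold(ContingencyTable(0, 50, 10, 90)) == 0.0

    def test_term_absent_from_whole_network_undefined(self):
        assert enrichment_fold(ContingencyTable(0, 50, 0, 100)) is None


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_correct([0.3]) == [pytest.approx(0.3)]

    def test_ties_preserved(self):
        assert bh_correct([0.5, 0.5]) == pytest.approx([0.5, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_correct([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    def test_permutation_equivariant_and_rank_monotone(self, ps, rnd):
        q = bh_correct(ps)
        assert all(qi >= pi - 1e-12 for pi, qi in zip(ps, q))
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        assert all(
            q[order[i]] <= q[order[i + 1]] + 1e-12 for i in range(len(order) - 1)
        )
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = bh_correct([ps[i] for i in perm])
        for j, i in enumerate(perm):
            assert q_perm[j] == pytest.approx(q[i])


def _two_term_graph():
    terms = {
        "R": InteractionTerm("R", "interaction"),
        "X": InteractionTerm("X", "x-type", ("R",)),
        "Y": InteractionTerm("Y", "y-type", ("R",)),
    }
    return OntologyGraph(terms=terms, root_id="R")


def _net(pair_counts: dict[str, int], docs_per_pair=1, graph=None, prefix="S"):
    """Build a network whose term X carries pair_counts['X'] unique pairs."""
    graph = graph or _two_term_graph()
    records = []
    i = 0
    for term, n in pair_counts.items():
        for k in range(n):
            pair = (f"{prefix}A{i:04d}", f"{prefix}B{i:04d}")
            for d in range(docs_per_pair):
                records.append(
                    InteractionRecord(f"D{d}_{i}", 0, pair, frozenset({term}))
                )
            i += 1
    return build_network(records, graph)


class TestBuildTable:
    def test_counts_follow_universe_and_term_sets(self):
        g = _two_term_graph()
        sub = _net({"X": 30, "Y": 150}, graph=g)
        whole = _net({"X": 1500, "Y": 30000}, graph=g)
        t = build_table("X", sub, whole)
        assert (t.a, t.b, t.A, t.B) == (30, 150, 1500, 30000)

    def test_term_absent_from_sub(self):
        g = _two_term_graph()
        sub = _net({"Y": 10}, graph=g)
        whole = _net({"X": 5, "Y": 20}, graph=g)
        t = build_table("X", sub, whole)
        assert (t.a, t.b) == (0, 10)

    def test_sub_equal_whole_gives_identical_columns(self):
        g = _two_term_graph()
        net = _net({"X": 7, "Y": 13}, graph=g)
        t = build_table("X", net, net)
        assert (t.a, t.b) == (t.A, t.B)

    def test_empty_subnetwork_raises(self):
        g = _two_term_graph()
        whole = _net({"X": 5}, graph=g)
        empty = AnnotatedNetwork()
        with pytest.raises(EmptySubnetworkError, match="empty sub-network"):
            build_table("X", empty, whole)


class TestRunEnrichment:
    def _sub_whole(self, sub_counts, whole_extra):
        """Whole network = sub records plus extra background records."""
        g = _two_term_graph()
        sub = _net(sub_counts, graph=g, prefix="S")
        extra = _net(whole_extra, graph=g, prefix="W")
        whole = AnnotatedNetwork(
            pairs_by_term={
                t: sub.pairs_by_term.get(t, set()) | extra.pairs_by_term.get(t, set())
                for t in set(sub.pairs_by_term) | set(extra.pairs_by_term)
            },
            universe=sub.universe | extra.universe,
            doc_count={**extra.doc_count, **sub.doc_count},
        )
        return sub, whole, g

    def test_min_pairs_filter_excludes_small_terms_from_bh(self):
        sub, whole, g = self._sub_whole({"X": 4, "Y": 50}, {"X": 10, "Y": 500})
        results = run_enrichment(sub, whole, g, min_pairs=5)
        assert "X" not in {r.term_id for r in results}

    def test_over_and_under_calls(self):
        sub, whole, g = self._sub_whole({"X": 30, "Y": 20}, {"X": 100, "Y": 5000})
        res = {r.term_id: r for r in run_enrichment(sub, whole, g)}
        assert res["X"].direction == "over"
        assert res["X"].fold > 2
        assert res["Y"].direction == "under"
        assert res["Y"].fold < 0.5

    def test_fold_one_never_called(self):
        sub, whole, g = self._sub_whole({"X": 50, "Y": 50}, {"X": 400, "Y": 400})
        res = {r.term_id: r for r in run_enrichment(sub, whole, g)}
        assert res["X"].direction == "none"

    def test_significant_but_small_fold_is_none(self):
        # p can be tiny while the fold stays under the 2x threshold
        sub, whole, g = self._sub_whole({"X": 900, "Y": 1100}, {"X": 3000, "Y": 7000})
        res = {r.term_id: r for r in run_enrichment(sub, whole, g)}
        assert res["X"].p_bh < 0.05
        assert res["X"].fold < 2
        assert res["X"].direction == "none"

    def test_never_both_directions_and_fold_agrees(self):
        sub, whole, g = self._sub_whole({"X": 40, "Y": 60}, {"X": 100, "Y": 4000})
        for r in run_enrichment(sub, whole, g):
            assert r.direction in {"over", "under", "none"}
            if r.direction == "over":
                assert r.fold > 1
            if r.direction == "under":
                assert r.fold < 1

    def test_pbh_never_below_praw(self):
        sub, whole, g = self._sub_whole({"X": 30, "Y": 150}, {"X": 100, "Y": 20000})
        for r in run_enrichment(sub, whole, g):
            assert r.p_bh >= r.p_raw - 1e-15

    def test_top_pair_is_most_documented_with_lexicographic_ties(self):
        g = _two_term_graph()
        records = [
            InteractionRecord("D1", 0, ("AA1", "AB1"), frozenset({"X"})),
            InteractionRecord("D2", 0, ("AA1", "AB1"), frozenset({"X"})),
            InteractionRecord("D3", 0, ("AC1", "AD1"), frozenset({"X"})),
        ] + [
            InteractionRecord(f"E{i}", 0, (f"BA{i}1", f"BB{i}1"), frozenset({"X"}))
            for i in range(5)
        ]
        sub = build_network(records, g)
        whole = sub
        res = {r.term_id: r for r in run_enrichment(sub, whole, g, min_pairs=1)}
        assert res["X"].top_pair == ("AA1", "AB1")
        assert res["X"].top_pair_docs == 2
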