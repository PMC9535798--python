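"""Cross-classification bookkeeping, overlaps, enrichment, volume."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.special import comb

from chipcross.expression import DEResult, bh_adjust
from chipcross.integrate import (
    LobeMeasurement,
    cross_classify,
    ellipsoid_volume,
    hypergeometric_enrichment,
    overlap_sets,
    percent_of_group,
    regulated_gene_set,
)
from chipcross.peaks import BindingCall


def call(gid, cls):
    supp = [] if cls == "unbound" else ["p"]
    d = None if cls == "unbound" else 10
    return BindingCall(gid, "f", cls, supp, d)


def de(gid, cls, lfc=None):
    if lfc is None:
        lfc = {"up": 2.0, "down": -2.0, "unchanged": 0.0}[cls]
    q = 0.001 if cls != "unchanged" else 0.9
    return DEResult(gid, 100.0, lfc, q, q, cls)


class TestCrossClassify:
    def test_four_gene_toy_matrix(self):
        binding = [call("a", "promoter"), call("b", "promoter"),
                   call("c", "unbound"), call("d", "nonpromoter_genic")]
        expr = [de("a", "up"), de("b", "unchanged"),
                de("c", "up"), de("d", "down")]
        table = cross_classify(binding, expr, ["a", "b", "c", "d"])
        assert table.counts == [[1, 0, 1], [0, 1, 0], [1, 0, 0]]
        assert table.universe_size == 4

    def test_all_unbound_unchanged_single_cell(self):
        ids = [f"g{i}" for i in range(7)]
        table = cross_classify(
            [call(g, "unbound") for g in ids],
            [de(g, "unchanged") for g in ids],
            ids,
        )
        assert table.count("unbound", "unchanged") == 7
        assert sum(sum(row) for row in table.counts) == 7

    def test_missing_de_defaults_to_unchanged(self):
        table = cross_classify(
            [call("a", "promoter")], [], ["a"]
        )
        assert table.per_gene["a"] == ("promoter", "unchanged")

    def test_duplicate_universe_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cross_classify([call("a", "unbound")], [], ["a", "a"])

    def test_counts_permutation_invariant(self, rng):
        ids = [f"g{i}" for i in range(60)]
        classes = rng.choice(
            ["promoter", "nonpromoter_genic", "unbound"], 60
        )
        exprs = rng.choice(["up", "down", "unchanged"], 60)
        binding = [call(g, c) for g, c in zip(ids, classes)]
        expr = [de(g, e) for g, e in zip(ids, exprs)]
        t1 = cross_classify(binding, expr, ids)
        perm = rng.permutation(60)
        t2 = cross_classify(
            [binding[i] for i in perm], [expr[i] for i in perm],
            [ids[i] for i in perm],
        )
        assert t1.counts == t2.counts


class TestPercent:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(1202, 7460, 16.1), (8525, 13951, 61.1), (0, 100, 0.0),
         (7460, 13951, 53.5), (154, 924, 16.7)],
    )
    def test_printed_style_rounding(self, k, n, expected):
        assert percent_of_group(k, n) == expected

    def test_half_away_from_zero(self):
        assert percent_of_group(125, 1000) == 12.5
        assert percent_of_group(1245, 10000) == 12.5  # 12.45 rounds up

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            percent_of_group(0, 0)


class TestRegulatedSets:
    def test_bound_up_only(self):
        binding = [call("a", "promoter"), call("b", "unbound"),
                   call("c", "nonpromoter_genic")]
        expr = [de("a", "up"), de("b", "up"), de("c", "down")]
        table = cross_classify(binding, expr, ["a", "b", "c"])
        assert regulated_gene_set(table, "up") == {"a"}
        assert regulated_gene_set(table, "down") == {"c"}

    def test_no_unbound_gene_in_regulated_union(self, rng):
        ids = [f"g{i}" for i in range(50)]
        classes = rng.choice(
            ["promoter", "nonpromoter_genic", "unbound"], 50
        )
        exprs = rng.choice(["up", "down", "unchanged"], 50)
        table = cross_classify(
            [call(g, c) for g, c in zip(ids, classes)],
            [de(g, e) for g, e in zip(ids, exprs)],
            ids,
        )
        union = regulated_gene_set(table, "up") | regulated_gene_set(
            table, "down"
        )
        unbound = {g for g, (b, _) in table.per_gene.items()
                   if b == "unbound"}
        assert not (union & unbound)


class TestOverlap:
    def test_published_venn_arithmetic(self):
        a = {f"a{i}" for i in range(1443)}
        b = {f"a{i}" for i in range(816)} | {f"b{i}" for i in range(165)}
        ov = overlap_sets(a, b)
        assert len(ov.shared) == 816
        assert len(ov.only_a) == 627
        assert len(ov.only_b) == 165

    def test_identical_sets(self):
        ov = overlap_sets({"x", "y"}, {"x", "y"})
        assert not ov.only_a and not ov.only_b and len(ov.shared) == 2

    def test_matches_membership_scan_oracle(self, rng):
        universe = [f"g{i}" for i in range(200)]
        a = {g for g in universe if rng.random() < 0.4}
        b = {g for g in universe if rng.random() < 0.4}
        ov = overlap_sets(a, b)
        for g in universe:
            in_a, in_b = g in a, g in b
            assert (g in ov.shared) == (in_a and in_b)
            assert (g in ov.only_a) == (in_a and not in_b)
            assert (g in ov.only_b) == (in_b and not in_a)


class TestEnrichment:
    def test_query_equals_universe_forced_overlap(self):
        u = {f"g{i}" for i in range(10)}
        res = hypergeometric_enrichment(u, {"t": set(u)}, u)
        assert res[0].p_value == pytest.approx(1.0)

    def test_closed_form_tail(self):
        # universe 20, term 5, query 5, overlap 5 -> p = 1/C(20,5)
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        res = hypergeometric_enrichment(term, {"t": term}, universe)
        assert res[0].p_value == pytest.approx(1 / comb(20, 5, exact=True))

    def test_matches_enumeration_oracle(self, rng):
        universe = [f"g{i}" for i in range(12)]
        term = set(rng.choice(universe, 5, replace=False))
        query = set(rng.choice(universe, 4, replace=False))
        res = hypergeometric_enrichment(
            query, {"t": term}, set(universe)
        )
        k_obs = len(term & query)
        total = hits = 0
        for draw in combinations(universe, len(query)):
            total += 1
            if len(term & set(draw)) >= k_obs:
                hits += 1
        assert res[0].p_value == pytest.approx(hits / total)

    def test_bh_consistent_with_bh_adjust(self, rng):
        universe = {f"g{i}" for i in range(100)}
        ann = {
            f"t{j}": set(rng.choice(sorted(universe), 20, replace=False))
            for j in range(8)
        }
        query = set(rng.choice(sorted(universe), 15, replace=False))
        res = hypergeometric_enrichment(query, ann, universe)
        p = [r.p_value for r in res]
        assert [r.q_value for r in res] == pytest.approx(bh_adjust(p))
        assert all(0 < r.p_value <= 1 for r in res)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"t": {"g"}}, set())


class TestEllipsoidVolume:
    def test_unit_sphere(self):
        assert ellipsoid_volume(LobeMeasurement(1, 1)) == pytest.approx(
            4 * math.pi / 3
        )

    def test_prolate_formula(self):
        assert ellipsoid_volume(LobeMeasurement(3, 2)) == pytest.approx(
            16 * math.pi
        )

    def test_degenerate_minor_axis(self):
        assert ellipsoid_volume(LobeMeasurement(2, 0)) == 0.0

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            LobeMeasurement(1, 2)  # minor exceeds major
        with pytest.raises(ValueError):
            LobeMeasurement(1, -0.5)
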