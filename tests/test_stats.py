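import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from netprio.graph_io import GeneList
from netprio.stats import (
    bh_adjust,
    hypergeom_tail,
    hypergeom_tail_p,
    ora_enrich,
    overlap_test,
    read_gmt,
    write_gmt,
)


def exact_tail(N: int, K: int, M: int, x: int) -> Fraction:
    """Big-rational upper-tail probability; shares no code with production."""
    upper = min(K, M)
    if x <= 0:
        return Fraction(1)
    if x > upper:
        return Fraction(0)
    num = sum(math.comb(M, j) * math.comb(N - M, K - j) for j in range(x, upper + 1))
    return Fraction(num, math.comb(N, K))


def enumerated_tail(N: int, K: int, M: int, x: int) -> Fraction:
    """Literal enumeration over all C(N, K) draws (tiny N only)."""
    hits = total = 0
    success = set(range(M))
    for draw in itertools.combinations(range(N), K):
        total += 1
        if len(success & set(draw)) >= x:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomTail:
    def test_small_case_against_literal_enumeration(self):
        # N=10, K=5, M=4, x=4 -> 1/42; enumeration validates the rational oracle too
        assert enumerated_tail(10, 5, 4, 4) == Fraction(1, 42)
        assert exact_tail(10, 5, 4, 4) == Fraction(1, 42)
        assert hypergeom_tail_p(10, 5, 4, 4) == pytest.approx(1 / 42, rel=1e-12)

    def test_x_zero_is_certain(self):
        assert hypergeom_tail(500, 30, 40, 0) == 0.0

    def test_x_above_support_is_impossible(self):
        assert hypergeom_tail(10, 3, 4, 5) == -math.inf

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 11, 3, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 3, -1, 1)

    @pytest.mark.parametrize("N", [1, 2, 5, 9, 14, 20, 26, 30])
    def test_matches_rational_oracle_over_full_parameter_grid(self, N):
        for K in range(N + 1):
            for M in range(N + 1):
                for x in range(min(K, M) + 2):
                    want = exact_tail(N, K, M, x)
                    got = hypergeom_tail_p(N, K, M, x)
                    assert got == pytest.approx(float(want), rel=1e-9, abs=1e-300)

    def test_pmf_sums_to_one_for_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(2, 501))
            K = int(rng.integers(0, N + 1))
            M = int(rng.integers(0, N + 1))
            # tail differences give the pmf; sum telescopes to P(X >= 0) = 1
            total = sum(
                hypergeom_tail_p(N, K, M, x) - hypergeom_tail_p(N, K, M, x + 1)
                for x in range(min(K, M) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_tail_non_increasing_in_x(self):
        vals = [hypergeom_tail(200, 50, 60, x) for x in range(0, 51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_exchangeable_in_K_and_M(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(2, 300))
            K = int(rng.integers(0, N + 1))
            M = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(K, M) + 1))
            assert hypergeom_tail(N, K, M, x) == pytest.approx(
                hypergeom_tail(N, M, K, x), rel=1e-12, abs=1e-12
            )

    def test_genome_scale_log_agrees_with_big_rational_oracle(self):
        """At universe scale (N ~ 2e4) the log-space sum must agree with the
        exact rational value to 3 significant digits in log10."""
        N, K, M, x = 19871, 742, 5583, 364
        want = exact_tail(N, K, M, x)
        want_log10 = math.log10(want.numerator) - math.log10(want.denominator)
        got_log10 = hypergeom_tail(N, K, M, x) / math.log(10)
        assert got_log10 == pytest.approx(want_log10, rel=5e-4)


class TestOverlapTest:
    def test_disjoint_lists_p_is_one(self):
        a = GeneList.from_iterable("a", ["A", "B"])
        b = GeneList.from_iterable("b", ["C", "D"])
        res = overlap_test(a, b, 100)
        assert res.observed_x == 0 and res.p_tail == 1.0

    def test_identical_lists_closed_form(self):
        a = GeneList.from_iterable("a", ["A", "B", "C"])
        res = overlap_test(a, a, 10)
        assert res.observed_x == 3
        assert res.p_tail == pytest.approx(1 / 120, rel=1e-12)

    def test_expected_value(self):
        a = GeneList.from_iterable("a", [f"A{i}" for i in range(20)])
        b = GeneList.from_iterable("b", [f"B{i}" for i in range(30)])
        res = overlap_test(a, b, 1000)
        assert res.expected == pytest.approx(20 * 30 / 1000)

    def test_universe_smaller_than_union_rejected(self):
        a = GeneList.from_iterable("a", ["A", "B", "C"])
        b = GeneList.from_iterable("b", ["D", "E"])
        with pytest.raises(ValueError):
            overlap_test(a, b, 4)

    def test_case_normalization_in_intersection(self):
        a = GeneList.from_iterable("a", ["tp53"])
        b = GeneList.from_iterable("b", ["TP53"])
        assert overlap_test(a, b, 10).observed_x == 1


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_step_up_hand_example(self):
        out = bh_adjust([0.005, 0.04, 0.8])
        assert np.allclose(out, [0.015, 0.06, 0.8])

    def test_equal_spaced_collapse(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_order_restored_and_capped(self):
        out = bh_adjust([0.9, 0.001, 0.5])
        assert out[1] == pytest.approx(0.003)
        assert out.max() <= 1.0


class TestOraEnrich:
    @pytest.fixture
    def universe(self):
        return GeneList.from_iterable("u", [f"G{i:03d}" for i in range(100)])

    def test_set_identical_to_query_is_most_significant(self, universe):
        query = GeneList.from_iterable("q", [f"G{i:03d}" for i in range(10)])
        coll = {
            "match": list(query),
            "other": [f"G{i:03d}" for i in range(50, 80)],
        }
        out = ora_enrich(query, coll, universe)
        assert out.iloc[0]["set_name"] == "match"
        want = hypergeom_tail_p(100, 10, 10, 10)
        assert out.iloc[0]["p_value"] == pytest.approx(want, rel=1e-12)

    def test_disjoint_set_p_is_one(self, universe):
        query = GeneList.from_iterable("q", [f"G{i:03d}" for i in range(10)])
        out = ora_enrich(query, {"far": [f"G{i:03d}" for i in range(60, 90)]}, universe)
        assert out.iloc[0]["p_value"] == 1.0

    def test_fdr_at_least_p_and_monotone(self, universe):
        rng = np.random.default_rng(3)
        query = GeneList.from_iterable("q", [f"G{i:03d}" for i in range(15)])
        coll = {
            f"s{j}": [f"G{i:03d}" for i in rng.choice(100, 20, replace=False)]
            for j in range(8)
        }
        out = ora_enrich(query, coll, universe)
        assert (out["bh_fdr"] >= out["p_value"] - 1e-15).all()
        assert (out["bh_fdr"].diff().dropna() >= -1e-15).all()

    def test_query_outside_universe_dropped_with_warning(self, universe):
        query = GeneList.from_iterable("q", ["G001", "NOT_THERE"])
        with pytest.warns(UserWarning, match="outside the universe"):
            out = ora_enrich(query, {"s": ["G001", "G002"]}, universe)
        assert len(out) == 1

    def test_empty_collection_warns(self, universe):
        query = GeneList.from_iterable("q", ["G001"])
        with pytest.warns(UserWarning, match="empty"):
            out = ora_enrich(query, {}, universe)
        assert out.empty

    def test_null_queries_are_super_uniform(self, universe):
        """Type-I error at alpha = 0.05 stays near or below nominal when the
        query is drawn uniformly from the universe."""
        rng = np.random.default_rng(4)
        members = [f"G{i:03d}" for i in range(40)]
        hits = 0
        reps = 2000
        for _ in range(reps):
            q = GeneList.from_iterable("q", (f"G{i:03d}" for i in rng.choice(100, 15, replace=False)))
            x = len(q.as_set & set(members))
            p = hypergeom_tail_p(100, 15, 40, x)
            if p <= 0.05:
                hits += 1
        assert hits / reps <= 0.07


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sets = {"SET_A": ("TP53", "TNF"), "SET_B": ("EGFR", "INS", "ESR1")}
        p = tmp_path / "x.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("NAME\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(p)

    def test_members_normalized_and_deduplicated(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S\tna\ttp53\tTP53\ttnf\n")
        assert read_gmt(p)["S"] == ("TP53", "TNF")
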