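import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialprev import (
    AreaCaseData,
    bernoulli_llr,
    distance_matrix,
    make_lattice_map,
    monte_carlo_pvalues,
    relative_risk,
    scan,
    secondary_clusters,
    window_sequence,
)
from spatialprev.geo import AreaMap
from spatialprev.scan import Cluster

from .conftest import line_map


def brute_force_best(data: AreaCaseData, amap: AreaMap, direction: str,
                     max_fraction: float = 0.5):
    """Exhaustive re-implementation: every centre, every nested radius,
    log terms evaluated one by one with math.log."""
    d = distance_matrix(amap)
    C, N = data.C, data.N
    overall = C / N

    def llr_terms(c, n):
        if n == N or n == 0:
            return 0.0
        rate = c / n
        if direction == "high" and rate <= overall:
            return 0.0
        if direction == "low" and rate >= overall:
            return 0.0
        co, no = C - c, N - n
        val = 0.0
        for num, den in ((c, n), (n - c, n), (co, no), (no - co, no)):
            if num > 0:
                val += num * math.log(num / den)
        for num, den in ((C, N), (N - C, N)):
            if num > 0:
                val -= num * math.log(num / den)
        return max(val, 0.0)

    best = (-1.0, None, None)  # llr, members, (c, n)
    for i in range(amap.n_areas):
        order = sorted(range(amap.n_areas), key=lambda j: (d[i, j], j))
        c = n = 0
        for m, j in enumerate(order):
            c += int(data.cases[j])
            n += int(data.totals[j])
            if m > 0 and n > max_fraction * N:
                break
            val = llr_terms(c, n)
            if val > best[0]:
                best = (val, tuple(amap.area_ids[x] for x in order[: m + 1]), (c, n))
    return best


def random_instance(rng, n_areas):
    cent = np.column_stack([rng.uniform(0, 3, n_areas), rng.uniform(0, 3, n_areas)])
    amap = AreaMap(tuple(f"z{i}" for i in range(n_areas)), cent,
                   {f"z{i}": frozenset() for i in range(n_areas)})
    totals = rng.integers(1, 12, n_areas)
    cases = rng.binomial(totals, rng.uniform(0.05, 0.6))
    return amap, AreaCaseData(amap.area_ids, cases, totals)


class TestBernoulliLLR:
    def test_null_rate_scores_zero(self):
        assert bernoulli_llr(1, 10, 10, 100, "high") == 0.0

    def test_worked_value(self):
        assert bernoulli_llr(5, 10, 10, 100, "high") == pytest.approx(6.2665, abs=1e-3)

    def test_one_sidedness_at_zero_cases(self):
        assert bernoulli_llr(0, 10, 10, 100, "low") > 0
        assert bernoulli_llr(0, 10, 10, 100, "high") == 0.0

    def test_whole_population_window_scores_zero(self):
        assert bernoulli_llr(10, 100, 10, 100, "high") == 0.0

    @given(st.integers(min_value=1, max_value=30), st.integers(min_value=2, max_value=40),
           st.integers(min_value=1, max_value=200), st.integers(min_value=2, max_value=400))
    @settings(max_examples=200, deadline=None)
    def test_directions_never_both_positive(self, c, n, C, N):
        if not (c <= n and c <= C and n < N and C <= N and C - c <= N - n):
            return
        hi = bernoulli_llr(c, n, C, N, "high")
        lo = bernoulli_llr(c, n, C, N, "low")
        assert hi >= 0 and lo >= 0
        assert not (hi > 0 and lo > 0)


class TestRelativeRisk:
    def test_worked_value(self):
        assert relative_risk(5, 10, 10, 100) == pytest.approx(9.0)

    def test_null_rate_unity(self):
        assert relative_risk(1, 10, 10, 100) == pytest.approx(1.0)

    def test_all_cases_inside_is_infinite(self):
        assert relative_risk(10, 20, 10, 100) == math.inf

    def test_zero_expectation_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            relative_risk(0, 0, 10, 100)


class TestWindowSequence:
    def _line_data(self, totals):
        amap = line_map(len(totals))
        return amap, AreaCaseData(amap.area_ids, np.zeros(len(totals), dtype=int),
                                  np.asarray(totals))

    def test_collinear_prefixes(self):
        amap, data = self._line_data([2, 10, 30])
        # windows grow outward along the line as nested prefixes under the cap
        wins = window_sequence("1", amap, data, max_fraction=0.5)
        assert wins == [("1",), ("1", "2")]

    def test_tiny_cap_keeps_center_only(self):
        amap, data = self._line_data([30, 10, 10])
        wins = window_sequence("1", amap, data, max_fraction=0.25)
        assert wins == [("1",)]

    def test_equidistant_tie_resolved_by_id_order(self):
        amap = line_map(3)  # area 2 is equidistant from 1 and 3
        data = AreaCaseData(amap.area_ids, [0, 0, 0], [1, 1, 4])
        wins = window_sequence("2", amap, data, max_fraction=0.5)
        assert wins[1] == ("2", "1")


class TestScan:
    def test_all_cases_in_one_area(self):
        amap = make_lattice_map(2, 3)
        cases = np.zeros(6, dtype=int)
        cases[4] = 10
        data = AreaCaseData(amap.area_ids, cases, np.full(6, 20))
        top = scan(data, amap, "high")[0]
        assert top.member_areas == (amap.area_ids[4],)
        assert top.observed == 10

    def test_uniform_rates_score_zero(self):
        amap = make_lattice_map(2, 2)
        data = AreaCaseData(amap.area_ids, [5, 5, 5, 5], [20, 20, 20, 20])
        assert scan(data, amap, "high") == []

    def test_all_zero_cases_empty_high_scan(self):
        amap = make_lattice_map(2, 2)
        data = AreaCaseData(amap.area_ids, [0, 0, 0, 0], [20, 20, 20, 20])
        assert scan(data, amap, "high") == []

    @pytest.mark.parametrize("direction", ["high", "low"])
    def test_matches_brute_force_enumeration(self, direction):
        rng = np.random.default_rng(314)
        checked = 0
        for _ in range(30):
            amap, data = random_instance(rng, int(rng.integers(3, 9)))
            if data.C == 0:
                continue
            oracle_llr, oracle_members, oracle_cn = brute_force_best(data, amap, direction)
            got = scan(data, amap, direction)
            if oracle_llr <= 0:
                assert got == []
                continue
            top = got[0]
            assert top.llr == pytest.approx(oracle_llr, abs=1e-9)
            assert top.member_areas == oracle_members
            c, n = oracle_cn
            assert top.relative_risk == pytest.approx(
                relative_risk(c, n, data.C, data.N))
            checked += 1
        assert checked >= 15

    def test_permutation_invariance_of_max_llr(self):
        rng = np.random.default_rng(99)
        amap, data = random_instance(rng, 7)
        base = scan(data, amap, "high")
        perm = rng.permutation(7)
        ids2 = tuple(f"z{i}" for i in range(7))
        amap2 = AreaMap(ids2, amap.centroids[perm],
                        {f"z{i}": frozenset() for i in range(7)})
        data2 = AreaCaseData(ids2, data.cases[perm], data.totals[perm])
        other = scan(data2, amap2, "high")
        if base:
            assert other[0].llr == pytest.approx(base[0].llr, abs=1e-9)
        else:
            assert other == []


class TestMonteCarlo:
    def test_p_floor_when_observed_beats_all(self):
        amap = make_lattice_map(2, 3)
        cases = np.array([0, 0, 0, 0, 30, 0])
        data = AreaCaseData(amap.area_ids, cases, np.full(6, 30))
        res = monte_carlo_pvalues(data, amap, "high", replications=999, seed=1)
        assert res[0].p_value == pytest.approx(1 / 1000)

    def test_uniform_data_yields_no_candidates(self):
        amap = make_lattice_map(2, 2)
        data = AreaCaseData(amap.area_ids, [5, 5, 5, 5], [20, 20, 20, 20])
        assert monte_carlo_pvalues(data, amap, "high", replications=99, seed=2) == []

    def test_deterministic_given_seed(self):
        amap = make_lattice_map(3, 3)
        rng = np.random.default_rng(5)
        cases = rng.binomial(25, 0.3, 9)
        data = AreaCaseData(amap.area_ids, cases, np.full(9, 25))
        a = monte_carlo_pvalues(data, amap, "high", replications=199, seed=7)
        b = monte_carlo_pvalues(data, amap, "high", replications=199, seed=7)
        assert [c.p_value for c in a] == [c.p_value for c in b]


class TestSecondaryClusters:
    def _cluster(self, members, llr, p, rank):
        return Cluster(center_area=members[0], member_areas=tuple(members),
                       observed=1, expected=1.0, llr=llr, relative_risk=2.0,
                       direction="high", p_value=p, rank=rank)

    def test_disjoint_clusters_both_reported(self):
        ranked = [self._cluster(["a", "b"], 10, 0.001, 1),
                  self._cluster(["c"], 5, 0.01, 2)]
        out = secondary_clusters(ranked)
        assert [c.rank for c in out] == [1, 2]

    def test_overlapping_candidate_suppressed(self):
        ranked = [self._cluster(["a", "b"], 10, 0.001, 1),
                  self._cluster(["b", "c"], 8, 0.002, 2),
                  self._cluster(["d"], 5, 0.01, 3)]
        out = secondary_clusters(ranked)
        assert [set(c.member_areas) for c in out] == [{"a", "b"}, {"d"}]

    def test_nothing_significant_empty_report(self):
        ranked = [self._cluster(["a"], 3, 0.2, 1)]
        assert secondary_clusters(ranked, 0.05) == []

    def test_missing_pvalues_rejected(self):
        cl = Cluster("a", ("a",), 1, 1.0, 3.0, 2.0, "high")
        with pytest.raises(ValueError, match="p-values"):
            secondary_clusters([cl])
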