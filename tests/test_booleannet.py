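import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from becc import (
    HIGH,
    INTERMEDIATE,
    LOW,
    QuadrantCounts,
    Relation,
    booleanize,
    classify_pair,
    quadrant_counts,
    scan_equivalents,
    sparsity_stat,
)
from becc.matrix import ExpressionMatrix


def sp_oracle(cells, i, j):
    """Direct re-evaluation of the sparsity formulas from first principles."""
    a00, a01, a10, a11 = cells
    total = a00 + a01 + a10 + a11
    grid = [[a00, a01], [a10, a11]]
    n = grid[i][j]
    row = grid[i][0] + grid[i][1]
    col = grid[0][j] + grid[1][j]
    nhat = (row / total) * (col / total) * total
    if nhat == 0:
        return 0.0, 0.0
    S = (nhat - n) / math.sqrt(nhat)
    p = 0.5 * (n / row + n / col)
    return S, p


def random_counts(rng, max_total=60):
    while True:
        cells = tuple(int(c) for c in rng.integers(0, max_total // 2, size=4))
        if sum(cells) > 0:
            return cells


class TestQuadrantCounts:
    def test_concordant_pair(self):
        c = quadrant_counts([LOW, LOW, HIGH, HIGH], [LOW, LOW, HIGH, HIGH])
        assert (c.a00, c.a01, c.a10, c.a11) == (2, 0, 0, 2)

    def test_intermediate_samples_dropped(self):
        c = quadrant_counts([LOW, INTERMEDIATE, HIGH], [HIGH, HIGH, LOW])
        assert (c.a00, c.a01, c.a10, c.a11) == (0, 1, 1, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            quadrant_counts([LOW, HIGH], [LOW])

    def test_all_intermediate_total_zero_classifies_none(self):
        c = quadrant_counts([INTERMEDIATE] * 5, [INTERMEDIATE] * 5)
        assert c.total == 0
        assert classify_pair(c).relation is Relation.NONE

    def test_marginals_consistent(self, rng):
        c = QuadrantCounts(*random_counts(rng))
        assert c.nAlow + c.nAhigh == c.total
        assert c.nBlow + c.nBhigh == c.total


class TestSparsityStat:
    def test_hand_checked_equivalence_case(self):
        c = QuadrantCounts(50, 0, 0, 50)
        for q in [(0, 1), (1, 0)]:
            st = sparsity_stat(c, q)
            assert st.nhat == pytest.approx(25.0)
            assert st.S == pytest.approx(5.0)
            assert st.p == 0.0

    def test_independence_case(self):
        c = QuadrantCounts(25, 25, 25, 25)
        for i in (0, 1):
            for j in (0, 1):
                st = sparsity_stat(c, (i, j))
                assert st.nhat == pytest.approx(25.0)
                assert st.S == pytest.approx(0.0)
                assert st.p == pytest.approx(0.5)

    def test_empty_marginal_is_undefined(self):
        st = sparsity_stat(QuadrantCounts(0, 0, 10, 10), (0, 0))
        assert st.undefined
        assert st.S == 0.0

    def test_total_zero_raises(self):
        with pytest.raises(ValueError):
            sparsity_stat(QuadrantCounts(0, 0, 0, 0), (0, 0))

    def test_matches_formula_oracle(self, rng):
        for _ in range(2000):
            cells = random_counts(rng)
            c = QuadrantCounts(*cells)
            i, j = int(rng.integers(2)), int(rng.integers(2))
            st = sparsity_stat(c, (i, j))
            S, p = sp_oracle(cells, i, j)
            if not st.undefined:
                assert st.S == pytest.approx(S, abs=1e-12)
                assert st.p == pytest.approx(p, abs=1e-12)


# constructed tables exhibiting each relation (min_total respected)
RELATION_CASES = [
    (QuadrantCounts(50, 0, 0, 50), Relation.EQUIVALENT),
    (QuadrantCounts(0, 50, 50, 0), Relation.OPPOSITE),
    (QuadrantCounts(40, 0, 40, 40), Relation.LOW_LOW),     # sparse a01
    (QuadrantCounts(0, 40, 40, 40), Relation.LOW_HIGH),    # sparse a00
    (QuadrantCounts(40, 40, 0, 40), Relation.HIGH_HIGH),   # sparse a10
    (QuadrantCounts(40, 40, 40, 0), Relation.HIGH_LOW),    # sparse a11
    (QuadrantCounts(25, 25, 25, 25), Relation.NONE),
]


class TestClassifyPair:
    @pytest.mark.parametrize("counts,expected", RELATION_CASES,
                             ids=[r.name for _, r in RELATION_CASES])
    def test_relation_taxonomy(self, counts, expected):
        assert classify_pair(counts).relation is expected

    @pytest.mark.parametrize("counts,expected", RELATION_CASES,
                             ids=[r.name for _, r in RELATION_CASES])
    def test_mirror_symmetry(self, counts, expected):
        mirror = {
            Relation.EQUIVALENT: Relation.EQUIVALENT,
            Relation.OPPOSITE: Relation.OPPOSITE,
            Relation.LOW_LOW: Relation.HIGH_HIGH,
            Relation.HIGH_HIGH: Relation.LOW_LOW,
            Relation.LOW_HIGH: Relation.LOW_HIGH,
            Relation.HIGH_LOW: Relation.HIGH_LOW,
            Relation.NONE: Relation.NONE,
        }
        assert classify_pair(counts.swapped()).relation is mirror[expected]

    def test_mirror_symmetry_random(self, rng):
        for _ in range(500):
            c = QuadrantCounts(*random_counts(rng, max_total=200))
            r_ab = classify_pair(c).relation
            r_ba = classify_pair(c.swapped()).relation
            sym = {Relation.EQUIVALENT, Relation.OPPOSITE, Relation.NONE,
                   Relation.LOW_HIGH, Relation.HIGH_LOW}
            if r_ab in sym:
                assert r_ba is r_ab
            else:
                assert {r_ab, r_ba} == {Relation.LOW_LOW, Relation.HIGH_HIGH}

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(min_value=0, max_value=60)] * 4))
    def test_stats_match_oracle_on_arbitrary_tables(self, cells):
        if sum(cells) == 0:
            return
        c = QuadrantCounts(*cells)
        for i in (0, 1):
            for j in (0, 1):
                st_ = sparsity_stat(c, (i, j))
                S, p = sp_oracle(cells, i, j)
                if not st_.undefined:
                    assert st_.S == pytest.approx(S, abs=1e-12)
                    assert st_.p == pytest.approx(p, abs=1e-12)

    def test_symmetric_takes_precedence_over_asymmetric(self):
        # both diagonal quadrants sparse: OPPOSITE, never a single-quadrant call
        res = classify_pair(QuadrantCounts(0, 50, 50, 1))
        assert res.relation is Relation.OPPOSITE

    def test_small_total_guard(self):
        res = classify_pair(QuadrantCounts(5, 0, 0, 5))
        assert res.relation is Relation.NONE
        assert "insufficient-samples" in res.flags

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_pair(QuadrantCounts(10, 10, 10, 10), s_threshold=-1)


class TestScanEquivalents:
    def test_planted_cluster_recovered(self, small_compendium):
        matrix, truth = small_compendium
        calls = booleanize(matrix)
        universal = truth.probes_with_label("universal")
        query = universal[0]
        found = scan_equivalents(calls, [query])[query]
        assert found == set(universal) - {query}

    def test_identical_probes_are_mutually_equivalent(self, rng):
        x = np.where(rng.random(100) < 0.5, 1.0, 5.0) + rng.normal(0, 0.1, 100)
        m = ExpressionMatrix(["A", "B"], [f"S{i}" for i in range(100)],
                             np.vstack([x, x]))
        calls = booleanize(m)
        found = scan_equivalents(calls, ["A", "B"])
        assert found["A"] == {"B"}
        assert found["B"] == {"A"}

    def test_constant_probe_has_no_equivalents(self, rng):
        x = np.where(rng.random(100) < 0.5, 1.0, 5.0)
        m = ExpressionMatrix(["A", "C"], [f"S{i}" for i in range(100)],
                             np.vstack([x, np.full(100, 3.0)]))
        calls = booleanize(m)
        assert scan_equivalents(calls, ["C"])["C"] == set()

    def test_unknown_query_raises(self, small_compendium):
        matrix, _ = small_compendium
        calls = booleanize(matrix)
        with pytest.raises(KeyError):
            scan_equivalents(calls, ["nope_at"])
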