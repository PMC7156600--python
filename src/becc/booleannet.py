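"""Boolean implication statistics for pairs of booleanized probes.

For a pair of binarized genes A and B, the samples where both calls are
informative (LOW or HIGH) fall into four quadrants with counts a00, a01,
a10 and a11 (first index = A's call, second = B's call).  A Boolean
implication holds when a quadrant is sparser than expected under
independence.  Sparsity of quadrant (i, j) is judged by

    S_ij = (nhat - n) / sqrt(nhat)        nhat = expected count
    p_ij = (a_ij/(a_i0 + a_i1) + a_ij/(a_0j + a_1j)) / 2

and a quadrant is sparse when S_ij > s_threshold and p_ij < p_threshold
(defaults 3 and 0.1).  Both off-diagonal quadrants sparse -> the genes
are Boolean *equivalent*; both diagonal quadrants sparse -> *opposite*;
exactly one sparse quadrant -> one of four asymmetric implications.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .stepminer import HIGH, LOW, BooleanCalls

__all__ = [
    "Relation",
    "QuadrantCounts",
    "QuadrantStat",
    "ImplicationResult",
    "quadrant_counts",
    "sparsity_stat",
    "classify_pair",
    "scan_equivalents",
    "DEFAULT_MIN_TOTAL",
]

# pairs with fewer informative samples than this are never classified
DEFAULT_MIN_TOTAL = 20


class Relation(enum.Enum):
    """The six Boolean implication relationships, plus NONE."""

    EQUIVALENT = "equivalent"
    OPPOSITE = "opposite"
    LOW_LOW = "low=>low"    # A low => B low   (sparse a01)
    LOW_HIGH = "low=>high"  # A low => B high  (sparse a00)
    HIGH_HIGH = "high=>high"  # A high => B high (sparse a10)
    HIGH_LOW = "high=>low"    # A high => B low  (sparse a11)
    NONE = "none"


# sparse quadrant (i, j) -> asymmetric relation
_SINGLE_QUADRANT_RELATION = {
    (0, 0): Relation.LOW_HIGH,
    (0, 1): Relation.LOW_LOW,
    (1, 0): Relation.HIGH_HIGH,
    (1, 1): Relation.HIGH_LOW,
}


@dataclass(frozen=True)
class QuadrantCounts:
    """Joint call counts for a probe pair over informative samples."""

    a00: int
    a01: int
    a10: int
    a11: int

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    @property
    def nAlow(self) -> int:
        return self.a00 + self.a01

    @property
    def nAhigh(self) -> int:
        return self.a10 + self.a11

    @property
    def nBlow(self) -> int:
        return self.a00 + self.a10

    @property
    def nBhigh(self) -> int:
        return self.a01 + self.a11

    def cell(self, i: int, j: int) -> int:
        return (self.a00, self.a01, self.a10, self.a11)[2 * i + j]

    def swapped(self) -> "QuadrantCounts":
        """Counts with the roles of A and B exchanged."""
        return QuadrantCounts(self.a00, self.a10, self.a01, self.a11)


@dataclass(frozen=True)
class QuadrantStat:
    """Sparsity statistics for one quadrant of a contingency table."""

    i: int
    j: int
    n: int                 # observed count a_ij
    nhat: float            # expected count under independence
    S: float               # (nhat - n)/sqrt(nhat); 0 when undefined
    p: float               # mean of the two conditional error rates
    undefined: bool        # True when nhat == 0 (an empty marginal)


@dataclass(frozen=True)
class ImplicationResult:
    """Classified Boolean relation for a probe pair."""

    relation: Relation
    counts: QuadrantCounts
    stats: tuple[QuadrantStat, QuadrantStat, QuadrantStat, QuadrantStat]
    s_threshold: float
    p_threshold: float
    flags: tuple[str, ...] = field(default=())

    def stat(self, i: int, j: int) -> QuadrantStat:
        return self.stats[2 * i + j]


def quadrant_counts(callsA, callsB) -> QuadrantCounts:
    """Count samples per quadrant, ignoring intermediate/missing calls.

    Only samples where *both* probes are called LOW or HIGH contribute.
    """
    a = np.asarray(callsA)
    b = np.asarray(callsB)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    both = ((a == LOW) | (a == HIGH)) & ((b == LOW) | (b == HIGH))
    a = a[both]
    b = b[both]
    return QuadrantCounts(
        a00=int(((a == LOW) & (b == LOW)).sum()),
        a01=int(((a == LOW) & (b == HIGH)).sum()),
        a10=int(((a == HIGH) & (b == LOW)).sum()),
        a11=int(((a == HIGH) & (b == HIGH)).sum()),
    )


def sparsity_stat(counts: QuadrantCounts, quadrant: tuple[int, int]) -> QuadrantStat:
    """Sparsity statistic and error rate for one quadrant.

    ``nhat`` is the count expected under independence of A and B.  When
    a marginal is empty ``nhat`` is 0 and the statistic is reported as 0
    with ``undefined=True`` (such a quadrant cannot attest sparsity).
    """
    i, j = quadrant
    if i not in (0, 1) or j not in (0, 1):
        raise ValueError(f"quadrant must be in {{0,1}}^2, got {quadrant}")
    total = counts.total
    if total == 0:
        raise ValueError("no informative samples: all calls intermediate/missing")
    n = counts.cell(i, j)
    marg_a = counts.cell(i, 0) + counts.cell(i, 1)  # samples with A == i
    marg_b = counts.cell(0, j) + counts.cell(1, j)  # samples with B == j
    nhat = marg_a * marg_b / total
    if nhat == 0.0:
        return QuadrantStat(i=i, j=j, n=n, nhat=0.0, S=0.0, p=0.0, undefined=True)
    S = (nhat - n) / np.sqrt(nhat)
    p = 0.5 * (n / marg_a + n / marg_b)
    return QuadrantStat(i=i, j=j, n=n, nhat=float(nhat), S=float(S), p=float(p),
                        undefined=False)


def classify_pair(
    counts: QuadrantCounts,
    s_threshold: float = 3.0,
    p_threshold: float = 0.1,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> ImplicationResult:
    """Classify a probe pair into one of the six relations or NONE.

    The symmetric relations take precedence: both off-diagonal quadrants
    sparse -> EQUIVALENT, both diagonal sparse -> OPPOSITE.  Otherwise a
    single sparse quadrant maps to its asymmetric implication.  Three or
    more sparse quadrants, or two sparse quadrants sharing a row/column,
    are pathological and yield NONE with a diagnostic flag, as does a
    pair with fewer than ``min_total`` informative samples.
    """
    if s_threshold <= 0 or not (0 < p_threshold < 1):
        raise ValueError("require s_threshold > 0 and 0 < p_threshold < 1")
    flags: list[str] = []
    if counts.total < min_total:
        stats = tuple(
            QuadrantStat(i=i, j=j, n=counts.cell(i, j), nhat=0.0, S=0.0, p=0.0,
                         undefined=True)
            for i in (0, 1) for j in (0, 1)
        ) if counts.total == 0 else tuple(
            sparsity_stat(counts, (i, j)) for i in (0, 1) for j in (0, 1)
        )
        flags.append("insufficient-samples")
        return ImplicationResult(Relation.NONE, counts, stats,
                                 s_threshold, p_threshold, tuple(flags))

    stats = tuple(sparsity_stat(counts, (i, j)) for i in (0, 1) for j in (0, 1))
    sparse = [
        (st.i, st.j)
        for st in stats
        if not st.undefined and st.S > s_threshold and st.p < p_threshold
    ]
    sset = set(sparse)
    if len(sparse) >= 3:
        relation = Relation.NONE
        flags.append("pathological-multi-sparse")
    elif {(0, 1), (1, 0)} <= sset:
        relation = Relation.EQUIVALENT
    elif {(0, 0), (1, 1)} <= sset:
        relation = Relation.OPPOSITE
    elif len(sparse) == 1:
        relation = _SINGLE_QUADRANT_RELATION[sparse[0]]
    elif len(sparse) == 2:
        relation = Relation.NONE
        flags.append("adjacent-sparse-pair")
    else:
        relation = Relation.NONE
    return ImplicationResult(relation, counts, stats,
                             s_threshold, p_threshold, tuple(flags))


def _batch_counts(query_calls: np.ndarray, codes: np.ndarray):
    """Quadrant counts of one query against every row of ``codes``.

    Returns four int arrays (a00, a01, a10, a11) of length n_probes.
    """
    q_low = query_calls == LOW
    q_high = query_calls == HIGH
    p_low = codes == LOW
    p_high = codes == HIGH
    a00 = p_low @ q_low.astype(np.int64)
    a01 = p_high @ q_low.astype(np.int64)
    a10 = p_low @ q_high.astype(np.int64)
    a11 = p_high @ q_high.astype(np.int64)
    return a00, a01, a10, a11


def scan_equivalents(
    calls: BooleanCalls,
    query_probes,
    s_threshold: float = 3.0,
    p_threshold: float = 0.1,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> dict[str, set[str]]:
    """For each query probe, find every other probe Boolean-equivalent to it.

    The scan vectorizes the quadrant counts of a query against all
    probes at once; classification then applies the standard rules per
    candidate.  Results do not depend on query order.
    """
    result: dict[str, set[str]] = {}
    probe_ids = calls.probe_ids
    for q in query_probes:
        qi = calls.probe_index(q)  # raises on unknown probe
        qc = calls.codes[qi]
        a00, a01, a10, a11 = _batch_counts(qc, calls.codes)
        equivalents: set[str] = set()
        for pi, pid in enumerate(probe_ids):
            if pi == qi:
                continue
            counts = QuadrantCounts(int(a00[pi]), int(a01[pi]),
                                    int(a10[pi]), int(a11[pi]))
            if counts.total < min_total:
                continue
            # cheap pre-screen: p01 >= a01/total, so a01 > total*p_thr
            # rules out a sparse (0,1); likewise for (1,0)
            if counts.a01 > counts.total * p_threshold or \
               counts.a10 > counts.total * p_threshold:
                continue
            res = classify_pair(counts, s_threshold, p_threshold, min_total)
            if res.relation is Relation.EQUIVALENT:
                equivalents.add(pid)
        result[q] = equivalents
    return result
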