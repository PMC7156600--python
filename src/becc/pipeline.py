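"""Seed expansion, pair scoring, rank-weighted gene scores and the
empirical null: the marker-mining pipeline.

Starting from a seed probe, Boolean-equivalence expansion is run for a
fixed number of rounds (default three): set A holds probes equivalent to
the seed, set B adds probes equivalent to any member of A, set C adds
probes equivalent to any member of B.  The final candidate list L
(C plus the seed) is scored pairwise with

    score = r^2 + s^2

where r is the Pearson correlation of the two probes' log2 values
(floored at 0) and s the least-squares slope symmetrized by the
reciprocal rule (if s > 1 use 1/s), also floored at 0, so score lies in
[0, 2].  Each row of the score matrix M is sorted ascending and combined
with rank weights 0..len(L)-1:

    gs_i = (1/len(L)) * sum_k k * score_ik / 2

High gs marks probes tightly co-expressed with the entire cluster.  A
one-step fit on the sorted gs values yields the selection threshold, and
an empirical null built from random probe pairs gives a Z-test p-value
for that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .booleannet import scan_equivalents
from .config import RunConfig
from .matrix import ExpressionMatrix, ProbeAnnotation
from .stepminer import BooleanCalls, booleanize, fit_step

__all__ = [
    "ExpansionTrace",
    "PairScore",
    "EmpiricalNull",
    "BeccResult",
    "expand_seed",
    "pair_score",
    "score_matrix",
    "gene_scores",
    "select_by_threshold",
    "empirical_null",
    "simulate_mean_gs",
    "run_becc",
]

logger = logging.getLogger("becc")


@dataclass
class ExpansionTrace:
    """Candidate sets after each equivalence-expansion round.

    ``set_a`` excludes the seed; ``candidates`` (the list L) is the last
    round's set plus the seed, ordered by the matrix's probe order.
    """

    seed: str
    set_a: set[str]
    set_b: set[str]
    set_c: set[str]
    candidates: list[str]
    step_sizes: list[int] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.set_a


@dataclass(frozen=True)
class PairScore:
    """Correlation/slope co-expression score for a probe pair.

    ``r`` is the Pearson correlation, ``s`` the symmetrized regression
    slope (reciprocal rule applied; never exceeds 1).  Both are floored
    at 0 before squaring, so ``score = r^2 + s^2`` lies in [0, 2] and
    anti-correlated pairs score near 0.
    """

    r: float
    s: float

    @property
    def score(self) -> float:
        return max(self.r, 0.0) ** 2 + max(self.s, 0.0) ** 2


def expand_seed(
    calls: BooleanCalls,
    seed_probe: str,
    steps: int = 3,
    s_threshold: float = 3.0,
    p_threshold: float = 0.1,
    min_total: int = 20,
) -> ExpansionTrace:
    """Grow the Boolean-equivalence neighborhood of a seed probe.

    Each round scans only the probes newly added in the previous round,
    unioning their equivalents into the frontier.  An uninformative seed
    (no LOW or no HIGH calls) is rejected; a seed with no equivalents
    yields an empty trace (the pipeline then returns an empty result).
    """
    calls.probe_index(seed_probe)  # raise early on unknown id
    if not calls.is_informative(seed_probe):
        raise ValueError(
            f"seed probe {seed_probe!r} has no LOW/HIGH dynamic; "
            "choose a different seed probeset"
        )
    if steps < 1:
        raise ValueError("steps must be >= 1")

    sets: list[set[str]] = []
    current: set[str] = set()
    frontier = [seed_probe]
    for step in range(steps):
        found = scan_equivalents(calls, frontier, s_threshold, p_threshold,
                                 min_total)
        new = set().union(*found.values()) if found else set()
        new.discard(seed_probe)
        frontier = sorted(new - current)
        current = current | new
        sets.append(set(current))
        logger.info("expansion step %d: %d probes", step + 1, len(current))
        if not frontier:
            # no new probes; later rounds cannot add anything
            while len(sets) < steps:
                sets.append(set(current))
            break

    set_a = sets[0]
    set_b = sets[1] if steps >= 2 else set(sets[0])
    set_c = sets[-1]
    order = {p: i for i, p in enumerate(calls.probe_ids)}
    candidates = sorted(set_c | {seed_probe}, key=order.__getitem__)
    if not set_a:
        logger.warning("seed %s has no Boolean-equivalent probes", seed_probe)
        candidates = []
    return ExpansionTrace(
        seed=seed_probe,
        set_a=set_a,
        set_b=set_b,
        set_c=set_c,
        candidates=candidates,
        step_sizes=[len(s) for s in sets],
    )


def _paired_observed(valuesA, valuesB, maskA=None, maskB=None):
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b)
    if maskA is not None:
        keep &= ~np.asarray(maskA, dtype=bool)
    if maskB is not None:
        keep &= ~np.asarray(maskB, dtype=bool)
    return a[keep], b[keep]


def pair_score(valuesA, valuesB, maskA=None, maskB=None) -> PairScore:
    """Score two probes' co-expression from raw log2 values.

    Uses all samples observed in both probes.  The slope is symmetrized:
    with s_ab the slope of B on A and s_ba the slope of A on B
    (s_ab * s_ba = r^2), the smaller of the two is kept, which equals
    the "if s > 1 use 1/s" rule for exact linear relations and makes the
    score independent of argument order.
    """
    a, b = _paired_observed(valuesA, valuesB, maskA, maskB)
    if a.size < 3:
        raise ValueError(f"need >= 3 paired samples, got {a.size}")
    var_a = float(np.var(a))
    var_b = float(np.var(b))
    if var_a == 0.0 or var_b == 0.0:
        raise ValueError("constant probe: correlation undefined")
    cov = float(np.mean((a - a.mean()) * (b - b.mean())))
    r = cov / np.sqrt(var_a * var_b)
    s = min(cov / var_a, cov / var_b)
    return PairScore(r=float(r), s=float(s))


def score_matrix(expr: ExpressionMatrix, candidates) -> np.ndarray:
    """Symmetric matrix of pair scores over the candidate list.

    The diagonal is the self-score 2; it enters every row's rank sum
    identically and cannot reorder probes.
    """
    L = list(candidates)
    idx = [expr.probe_index(p) for p in L]
    n = len(L)
    M = np.full((n, n), 2.0)
    for a in range(n):
        for b in range(a + 1, n):
            ps = pair_score(
                expr.values[idx[a]], expr.values[idx[b]],
                expr.mask[idx[a]], expr.mask[idx[b]],
            )
            M[a, b] = M[b, a] = ps.score
    return M


def gene_scores(M: np.ndarray) -> np.ndarray:
    """Rank-weighted gene score per row of the score matrix.

    Each row (diagonal included) is sorted ascending and dotted with the
    rank vector [0, 1, ..., len-1]; gs_i = that sum / (2 * len).  Bounds:
    0 <= gs_i <= (len - 1) / 2, with equality when every score is 2.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("score matrix must be square")
    n = M.shape[0]
    ranks = np.arange(n, dtype=float)
    rows = np.sort(M, axis=1)
    return rows @ ranks / (2.0 * n)


def _step_r2_null(n: int, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the step fit's ssr/sst on sorted iid Gaussians.

    The ratio is location/scale free, so a standard normal suffices.
    Sorted homogeneous data always admits *some* step, which makes the
    naive fit look structured; this reference distribution says how
    structured is expected by chance.
    """
    draws = np.sort(rng.standard_normal((n_sim, n)), axis=1)
    csum = np.cumsum(draws, axis=1)
    csum2 = np.cumsum(draws**2, axis=1)
    total = csum[:, -1:]
    total2 = csum2[:, -1]
    k = np.arange(1, n)
    sum_low = csum[:, :-1]
    sse = total2[:, None] - sum_low**2 / k - (total - sum_low) ** 2 / (n - k)
    sst = total2 - total[:, 0] ** 2 / n
    best_sse = sse.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - best_sse / sst
    return np.clip(r2, 0.0, 1.0)


def select_by_threshold(
    gs: np.ndarray,
    homogeneity_alpha: float = 0.001,
    n_null: int = 999,
) -> tuple[float, np.ndarray]:
    """One-step-fit threshold on the gs values; select scores above it.

    Returns ``(threshold, selected)`` with ``selected`` a boolean array
    aligned to ``gs``.  Constant gs (degenerate fit) selects everything.

    Because the gs values are sorted before fitting, a step fit always
    "finds" a split even in a single homogeneous cluster.  The fitted
    split is therefore applied only when its explained-variance ratio
    ssr/sst is significantly larger (one-sided parametric bootstrap,
    level ``homogeneity_alpha``) than for sorted iid Gaussian values of
    the same length; otherwise the gs list is one cluster of
    high-scorers and every candidate is selected.
    """
    gs = np.asarray(gs, dtype=float)
    if gs.size < 2:
        raise ValueError("need at least 2 gene scores to threshold")
    fit = fit_step(gs)
    sst = fit.ssr + fit.sse
    if sst == 0.0:
        logger.warning("constant gene scores: selecting all probes")
        return fit.threshold, np.ones_like(gs, dtype=bool)
    r2_obs = fit.ssr / sst
    rng = np.random.default_rng(1729)  # fixed: the test must be reproducible
    r2_null = _step_r2_null(gs.size, n_null, rng)
    p_step = (1.0 + (r2_null >= r2_obs).sum()) / (n_null + 1.0)
    if p_step > homogeneity_alpha:
        logger.info(
            "no significant step in gene scores (p=%.3f): one cluster, "
            "selecting all %d probes", p_step, gs.size,
        )
        return fit.threshold, np.ones_like(gs, dtype=bool)
    return fit.threshold, gs > fit.threshold


@dataclass
class EmpiricalNull:
    """Null distribution of the pair score over random probe pairs.

    ``e_gs`` and ``sd_gs`` follow the rank-weight identity
    E[gs] = E[score] * (len(L) - 1) / 4 and its standard-deviation
    analogue; both treat each rank's score as an exchangeable draw from
    the pairwise score distribution (an approximation: sorting induces
    order-statistic dependence that the identity ignores).
    """

    mean_score: float
    var_score: float
    n_pairs: int
    rng_seed: int
    len_L: int
    e_gs: float
    sd_gs: float
    z: float | None = None
    p_value: float | None = None

    def z_test(self, gs_threshold: float) -> tuple[float, float]:
        """One-sided (upper-tail) Z-test of a gs threshold against the null."""
        if self.sd_gs == 0.0:
            z = float("inf") if gs_threshold > self.e_gs else float("-inf")
        else:
            z = (gs_threshold - self.e_gs) / self.sd_gs
        return float(z), float(sps.norm.sf(z))


def _sample_pair_scores(
    expr: ExpressionMatrix, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """Scores of ``n_pairs`` distinct random probe pairs.

    Constant probes and pairs with < 3 complete observations are
    excluded (their correlation is undefined).  Sampling is without
    replacement among unordered pairs of eligible probes.
    """
    has_missing = bool(expr.mask.any())
    if has_missing:
        obs_counts = (~expr.mask).sum(axis=1)
        variances = np.array([
            np.var(expr.values[i][~expr.mask[i]]) if obs_counts[i] >= 3 else 0.0
            for i in range(expr.n_probes)
        ])
        eligible = np.flatnonzero((obs_counts >= 3) & (variances > 0))
    else:
        eligible = np.flatnonzero(expr.values.var(axis=1) > 0)
    P = eligible.size
    if P < 2:
        raise ValueError("need at least 2 non-constant probes for the null")
    total_pairs = P * (P - 1) // 2
    k = min(n_pairs, total_pairs)
    chosen = rng.choice(total_pairs, size=k, replace=False)
    # decode unordered pair index: i = row in the strict upper triangle
    i = (P - 2 - np.floor(
        np.sqrt(-8.0 * chosen + 4 * P * (P - 1) - 7) / 2.0 - 0.5)).astype(np.int64)
    j = (chosen + i + 1 - P * (P - 1) // 2 + (P - i) * (P - i - 1) // 2).astype(np.int64)
    pi = eligible[i]
    pj = eligible[j]

    if has_missing:
        scores = np.empty(k)
        for t in range(k):
            try:
                scores[t] = pair_score(
                    expr.values[pi[t]], expr.values[pj[t]],
                    expr.mask[pi[t]], expr.mask[pj[t]],
                ).score
            except ValueError:
                scores[t] = np.nan
        return scores[np.isfinite(scores)]

    X = expr.values
    means = X.mean(axis=1)
    xc_var = X.var(axis=1)
    scores = np.empty(k)
    chunk = 8192
    nsamp = expr.n_samples
    for start in range(0, k, chunk):
        sl = slice(start, min(start + chunk, k))
        A = X[pi[sl]] - means[pi[sl], None]
        B = X[pj[sl]] - means[pj[sl], None]
        cov = (A * B).mean(axis=1)
        va = xc_var[pi[sl]]
        vb = xc_var[pj[sl]]
        r = cov / np.sqrt(va * vb)
        s = np.minimum(cov / va, cov / vb)
        scores[sl] = np.maximum(r, 0.0) ** 2 + np.maximum(s, 0.0) ** 2
    del nsamp
    return scores


def empirical_null(
    expr: ExpressionMatrix,
    n_pairs: int,
    rng_seed: int,
    len_L: int,
    gs_threshold: float | None = None,
) -> EmpiricalNull:
    """Estimate the pair-score null and derive the gs null moments.

    Pairs are drawn uniformly without replacement among distinct probe
    pairs; the gs moments use E[gs] = E[score]*(len(L)-1)/4 and
    sd(gs) = sd(score)*(len(L)-1)/4.  When ``gs_threshold`` is given the
    one-sided Z-test is evaluated and stored.
    """
    if expr.n_probes < 2:
        raise ValueError("need at least 2 probes")
    rng = np.random.default_rng(rng_seed)
    scores = _sample_pair_scores(expr, n_pairs, rng)
    mean_score = float(scores.mean())
    var_score = float(scores.var(ddof=1)) if scores.size > 1 else 0.0
    factor = (len_L - 1) / 4.0
    null = EmpiricalNull(
        mean_score=mean_score,
        var_score=var_score,
        n_pairs=int(scores.size),
        rng_seed=int(rng_seed),
        len_L=int(len_L),
        e_gs=mean_score * factor,
        sd_gs=float(np.sqrt(var_score)) * factor,
    )
    if gs_threshold is not None:
        null.z, null.p_value = null.z_test(gs_threshold)
    return null


def simulate_mean_gs(
    score_samples: np.ndarray,
    len_L: int,
    n_rows: int,
    rng: np.random.Generator,
    n_se_rows: int = 4000,
) -> tuple[float, float]:
    """Monte-Carlo mean gs for rows of iid scores.

    Draws ``n_rows`` rows of ``len_L`` scores (with replacement) from
    the empirical score sample, applies the sort-then-rank-weight gs
    formula to each row, and returns ``(mean, standard error)``.  Serves
    as the simulation check of the analytic E[gs] identity.

    The pair-score distribution is typically a near-zero mass with a
    thin tail of genuinely co-expressed pairs near 2, so a small row
    sample badly underestimates its own dispersion; the standard error
    of the ``n_rows`` mean is therefore estimated from ``n_se_rows``
    auxiliary rows.
    """
    samples = np.asarray(score_samples, dtype=float)
    draws = rng.choice(samples, size=(n_rows, len_L), replace=True)
    gs = gene_scores_rows(draws)
    aux = gene_scores_rows(rng.choice(samples, size=(n_se_rows, len_L),
                                      replace=True))
    se = float(aux.std(ddof=1) / np.sqrt(n_rows))
    return float(gs.mean()), se


def gene_scores_rows(rows: np.ndarray) -> np.ndarray:
    """gs formula applied to arbitrary (not necessarily square) rows."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[1]
    ranks = np.arange(n, dtype=float)
    return np.sort(rows, axis=1) @ ranks / (2.0 * n)


@dataclass
class BeccResult:
    """Complete output of a marker-mining run."""

    trace: ExpansionTrace
    candidates: list[str]
    M: np.ndarray | None
    gs: np.ndarray | None
    gs_threshold: float | None
    selected: list[str]
    genes: list[str]
    null: EmpiricalNull | None
    dynamic_range: dict[str, float]
    status: str = "ok"

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def run_becc(
    expr: ExpressionMatrix,
    config: RunConfig,
    annotation: ProbeAnnotation | None = None,
) -> BeccResult:
    """Run the full pipeline: booleanize, expand, score, threshold, test.

    Returns an empty result (status ``"empty-expansion"``) when the seed
    has no Boolean-equivalent probes.
    """
    calls = booleanize(expr, margin=config.noise_margin)
    trace = expand_seed(
        calls,
        config.seed_probe,
        steps=config.expansion_steps,
        s_threshold=config.s_threshold,
        p_threshold=config.p_threshold,
        min_total=config.min_informative,
    )
    logger.info(
        "expansion sizes |A|=%d |B|=%d |C|=%d",
        len(trace.set_a), len(trace.set_b), len(trace.set_c),
    )
    if trace.is_empty:
        return BeccResult(
            trace=trace, candidates=[], M=None, gs=None, gs_threshold=None,
            selected=[], genes=[], null=None, dynamic_range={},
            status="empty-expansion",
        )

    L = trace.candidates
    M = score_matrix(expr, L)
    gs = gene_scores(M)
    gs_threshold, selected_mask = select_by_threshold(gs)
    selected = [p for p, keep in zip(L, selected_mask) if keep]
    null = empirical_null(
        expr, config.null_pairs, config.rng_seed, len(L), gs_threshold
    )
    genes = annotation.unique_genes(selected) if annotation is not None else []
    dyn = {p: expr.dynamic_range(p) for p in L}
    logger.info(
        "|L|=%d selected=%d threshold=%.4f Z=%.2f p=%.3g",
        len(L), len(selected), gs_threshold, null.z, null.p_value,
    )
    return BeccResult(
        trace=trace, candidates=L, M=M, gs=gs, gs_threshold=gs_threshold,
        selected=selected, genes=genes, null=null, dynamic_range=dyn,
    )
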