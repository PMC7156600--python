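"""Marker-validation statistics.

Three checks used to validate candidate universal markers:

* the fraction of samples (or single cells) where a gene pair is
  high-high, with per-gene thresholds at the middle of the observed
  range or from the step fit;
* a two-sided variance-ratio F-test comparing a candidate's expression
  stability against reference markers in purified populations;
* ranking of candidate genes by Pearson correlation with a reference
  gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .matrix import ExpressionMatrix
from .stepminer import threshold_probe

__all__ = [
    "HighHighReport",
    "VariabilityComparison",
    "high_high_fraction",
    "variance_ftest",
    "correlation_ranking",
]


@dataclass(frozen=True)
class HighHighReport:
    """Quadrant occupancy of a gene pair at per-gene thresholds."""

    gene_a: str
    gene_b: str
    threshold_a: float
    threshold_b: float
    threshold_mode: str
    n_low_low: int
    n_low_high: int
    n_high_low: int
    n_high_high: int

    @property
    def n(self) -> int:
        return (self.n_low_low + self.n_low_high
                + self.n_high_low + self.n_high_high)

    @property
    def fraction_high_high(self) -> float:
        return self.n_high_high / self.n if self.n else float("nan")


def _paired(a, b, mask_a=None, mask_b=None):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask_a is not None:
        keep &= ~np.asarray(mask_a, dtype=bool)
    if mask_b is not None:
        keep &= ~np.asarray(mask_b, dtype=bool)
    return a[keep], b[keep]


def high_high_fraction(
    exprA,
    exprB,
    threshold_mode: str = "midrange",
    gene_a: str = "A",
    gene_b: str = "B",
    mask_a=None,
    mask_b=None,
) -> HighHighReport:
    """Fraction of paired samples with both genes above threshold.

    ``threshold_mode="midrange"`` places each gene's threshold at
    (min + max)/2 of its observed values (the "middle of the range");
    ``"stepminer"`` uses the step-fit midpoint.  "High" is strict
    inequality above the threshold.
    """
    a, b = _paired(exprA, exprB, mask_a, mask_b)
    if a.size == 0:
        raise ValueError("no paired observations")
    if threshold_mode == "midrange":
        if a.min() == a.max() or b.min() == b.max():
            raise ValueError("constant gene: midrange threshold undefined")
        ta = 0.5 * (a.min() + a.max())
        tb = 0.5 * (b.min() + b.max())
    elif threshold_mode == "stepminer":
        ta = threshold_probe(a)
        tb = threshold_probe(b)
    else:
        raise ValueError("threshold_mode must be 'midrange' or 'stepminer'")
    hi_a = a > ta
    hi_b = b > tb
    return HighHighReport(
        gene_a=gene_a,
        gene_b=gene_b,
        threshold_a=float(ta),
        threshold_b=float(tb),
        threshold_mode=threshold_mode,
        n_low_low=int((~hi_a & ~hi_b).sum()),
        n_low_high=int((~hi_a & hi_b).sum()),
        n_high_low=int((hi_a & ~hi_b).sum()),
        n_high_high=int((hi_a & hi_b).sum()),
    )


@dataclass(frozen=True)
class VariabilityComparison:
    """Variance-ratio comparison of a candidate against a reference."""

    candidate: str
    reference: str
    sd_candidate: float
    sd_reference: float
    f_statistic: float   # larger variance / smaller variance, >= 1
    p_value: float
    degenerate: bool = False


def variance_ftest(
    values_candidate,
    values_reference,
    candidate: str = "candidate",
    reference: str = "reference",
) -> VariabilityComparison:
    """Two-sided F-test for equality of two genes' variances.

    The statistic is the larger sample variance over the smaller, with
    (n-1, n-1) degrees of freedom per gene; the two-sided p-value is
    twice the upper tail.  Zero variance in either gene yields a
    sentinel p-value with the degenerate flag set.
    """
    x = np.asarray(values_candidate, dtype=float)
    y = np.asarray(values_reference, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 observations per gene")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    sdx, sdy = float(np.sqrt(vx)), float(np.sqrt(vy))
    if vx == 0.0 or vy == 0.0:
        return VariabilityComparison(
            candidate=candidate, reference=reference,
            sd_candidate=sdx, sd_reference=sdy,
            f_statistic=float("inf"), p_value=float("nan"), degenerate=True,
        )
    if vx >= vy:
        f = vx / vy
        dfn, dfd = x.size - 1, y.size - 1
    else:
        f = vy / vx
        dfn, dfd = y.size - 1, x.size - 1
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return VariabilityComparison(
        candidate=candidate, reference=reference,
        sd_candidate=sdx, sd_reference=sdy,
        f_statistic=float(f), p_value=p,
    )


def correlation_ranking(
    expr: ExpressionMatrix,
    reference_gene: str,
    candidate_genes,
) -> list[tuple[str, float]]:
    """Rank candidates by Pearson correlation with a reference gene.

    Returns ``(gene, r)`` pairs sorted by r descending, ties broken by
    gene id; candidates with undefined correlation (constant values)
    carry ``nan`` and sort last.
    """
    ref_v, ref_m = expr.probe_values(reference_gene)
    results: list[tuple[str, float]] = []
    for gene in candidate_genes:
        v, m = expr.probe_values(gene)
        a, b = _paired(ref_v, v, ref_m, m)
        if a.size < 3 or np.var(a) == 0.0 or np.var(b) == 0.0:
            results.append((gene, float("nan")))
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        results.append((gene, r))
    defined = sorted(
        (g for g in results if np.isfinite(g[1])),
        key=lambda t: (-t[1], t[0]),
    )
    undefined = sorted((g for g in results if not np.isfinite(g[1])),
                       key=lambda t: t[0])
    return defined + undefined
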