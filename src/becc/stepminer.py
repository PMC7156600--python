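"""Rising one-step function fits and expression booleanization.

A gene's expression values, sorted ascending, typically show a sharp
transition between an "off" level and an "on" level.  Fitting a one-step
function (two constant segments) by least squares locates that
transition; the midpoint of the two segment means is the per-gene
threshold used to binarize expression.  A noise margin around the
threshold (default ±0.5 log2 units, i.e. a twofold band) marks
borderline values as intermediate so they can be excluded from Boolean
pair statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "StepFit",
    "BooleanCalls",
    "LOW",
    "HIGH",
    "INTERMEDIATE",
    "MISSING",
    "fit_step",
    "threshold_probe",
    "booleanize",
]

# ternary call codes (int8); MISSING is carried separately from the calls
LOW = 0
HIGH = 1
INTERMEDIATE = 2
MISSING = 3

CALL_LABELS = {LOW: "0", HIGH: "1", INTERMEDIATE: "I", MISSING: "NA"}

_SSE_TOL = 1e-12


@dataclass(frozen=True)
class StepFit:
    """Least-squares rising one-step fit to sorted values.

    Attributes
    ----------
    n : number of values fitted.
    k : step position — count of values in the low segment (1..n-1).
    mu_low, mu_high : means of the low and high segments.
    threshold : (mu_low + mu_high) / 2, the booleanization threshold.
    sse : residual sum of squares of the fit.
    ssr : explained sum of squares about the grand mean.
    m : degrees of freedom of the adaptive fit (two means + step position).
    fstat : [ssr/(m-1)] / [sse/(n-m)]; +inf when sse == 0 (degenerate).
    degenerate : True when the fit is uninformative (sse == 0, e.g. a
        constant vector, or n too small for the F ratio).
    """

    n: int
    k: int
    mu_low: float
    mu_high: float
    threshold: float
    sse: float
    ssr: float
    m: int
    fstat: float
    degenerate: bool


def fit_step(values, already_sorted: bool = False, m: int = 3) -> StepFit:
    """Fit a rising step to ``values`` minimizing sum of squared error.

    All step positions ``k`` in ``[1, n-1]`` are evaluated in one pass
    via prefix sums; ties on sse are broken by the smallest ``k``.

    Parameters
    ----------
    values
        At least two finite values; sorted ascending internally unless
        ``already_sorted``.
    m
        Degrees of freedom charged to the adaptive fit when forming the
        F statistic.  The F statistic is diagnostic only; threshold
        selection does not depend on it.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 values to fit a step, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("fit_step requires finite values (drop missing first)")
    if not already_sorted:
        x = np.sort(x, kind="stable")

    n = x.size
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    total = csum[-1]
    total2 = csum2[-1]
    xbar = total / n

    k = np.arange(1, n)  # low-segment sizes
    sum_low = csum[:-1]
    sum_high = total - sum_low
    # sse(k) = (sum of squares) - (segment-mean explained part), per segment
    sse_all = (total2) - sum_low**2 / k - sum_high**2 / (n - k)
    best = int(np.argmin(sse_all))  # argmin returns first minimum: smallest k
    kbest = best + 1
    sse = float(max(sse_all[best], 0.0))

    mu_low = float(sum_low[best] / kbest)
    mu_high = float(sum_high[best] / (n - kbest))
    ssr = float(kbest * (mu_low - xbar) ** 2 + (n - kbest) * (mu_high - xbar) ** 2)
    threshold = 0.5 * (mu_low + mu_high)

    degenerate = False
    if sse <= _SSE_TOL * max(1.0, total2):
        fstat = float("inf")
        degenerate = True
    elif n <= m:
        fstat = float("nan")
        degenerate = True
    else:
        fstat = (ssr / (m - 1)) / (sse / (n - m))
    return StepFit(
        n=n,
        k=kbest,
        mu_low=mu_low,
        mu_high=mu_high,
        threshold=threshold,
        sse=sse,
        ssr=ssr,
        m=m,
        fstat=float(fstat),
        degenerate=degenerate,
    )


def threshold_probe(values) -> float:
    """Booleanization threshold for one probe: the step-fit midpoint."""
    return fit_step(values).threshold


@dataclass
class BooleanCalls:
    """Ternary (low / intermediate / high) calls for a booleanized matrix.

    ``codes`` uses the module-level constants ``LOW``, ``HIGH``,
    ``INTERMEDIATE`` and ``MISSING``.  A call is LOW iff
    ``value < threshold - margin``, HIGH iff ``value > threshold +
    margin``; values inside the closed margin band (boundaries included)
    are INTERMEDIATE.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    codes: np.ndarray  # int8, shape (n_probes, n_samples)
    thresholds: np.ndarray  # float, per probe; NaN when degenerate
    margin: float

    def __post_init__(self) -> None:
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_index[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id: {probe_id!r}") from None

    def calls_for(self, probe_id: str) -> np.ndarray:
        return self.codes[self.probe_index(probe_id)]

    def threshold_for(self, probe_id: str) -> float:
        return float(self.thresholds[self.probe_index(probe_id)])

    def is_informative(self, probe_id: str) -> bool:
        """True when the probe has both LOW and HIGH calls."""
        c = self.calls_for(probe_id)
        return bool((c == LOW).any() and (c == HIGH).any())


def booleanize(matrix: ExpressionMatrix, margin: float = 0.5) -> BooleanCalls:
    """Convert an expression matrix to ternary calls.

    Each probe gets its own step-fit threshold from its observed values;
    missing entries stay missing.  Probes with fewer than two observed
    values get no threshold (NaN) and all-INTERMEDIATE calls.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    n_probes, n_samples = matrix.shape
    codes = np.full((n_probes, n_samples), INTERMEDIATE, dtype=np.int8)
    thresholds = np.full(n_probes, np.nan)
    for i in range(n_probes):
        miss = matrix.mask[i]
        obs = matrix.values[i][~miss]
        if obs.size >= 2:
            thresholds[i] = fit_step(obs).threshold
            v = matrix.values[i]
            codes[i][v < thresholds[i] - margin] = LOW
            codes[i][v > thresholds[i] + margin] = HIGH
        codes[i][miss] = MISSING
    return BooleanCalls(
        probe_ids=list(matrix.probe_ids),
        sample_ids=list(matrix.sample_ids),
        codes=codes,
        thresholds=thresholds,
        margin=float(margin),
    )
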