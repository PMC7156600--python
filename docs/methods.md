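# Methods

This note documents the model, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## The step fit and booleanization

A gene's expression across a heterogeneous compendium is treated as
bimodal on the log2 scale: an "off" level (background/unexpressed) and
an "on" level. Sorting the values ascending and fitting a rising
one-step function — two constant segments, chosen to minimize the
residual sum of squares over all n−1 step positions — locates the
transition; the threshold is the midpoint of the two segment means. The
fit is computed with prefix sums in O(n) after the sort; ties on sse are
broken toward the smallest step index for determinism.

The fit's F statistic, [ssr/(m−1)]/[sse/(n−m)], is reported for
diagnostics with m = 3 degrees of freedom (two segment means plus the
step position); no significance filter is applied to it — downstream
stages consume only the threshold. A constant gene has sse = 0; its F is
reported as +inf with a degenerate flag rather than raising, because
large compendia do contain flat probes. Missing values are dropped
before fitting; a probe with fewer than two observed values gets no
threshold and all-intermediate calls.

Calls: LOW below threshold − margin, HIGH above threshold + margin,
INTERMEDIATE inside the closed band (boundary values inclusive — the
conservative choice, keeping borderline samples out of the quadrant
counts). The default margin of 0.5 log2 units is a twofold-change band.

## Implication statistics

For a pair, only samples with both calls in {LOW, HIGH} count. With
quadrant counts a_ij (first index = first gene), expected count
n̂ = (a_i·)(a_·j)/total, the sparsity statistic is S_ij = (n̂ − a_ij)/√n̂
(a z-score-like standardization of the deficit) and the error rate
p_ij = ½(a_ij/a_i· + a_ij/a_·j), the mean of the two conditional
probabilities of landing in the quadrant given each gene's relevant
state. A quadrant is sparse when S > 3 and p < 0.1 (strict
inequalities). Defensive rules where the statistics are undefined or
pathological:

* n̂ = 0 (an empty marginal): S reported as 0 with an undefined flag and
  the quadrant treated as non-sparse — sparsity cannot be attested
  without an expectation.
* fewer than 20 informative samples (configurable): the pair is NONE;
  tiny tables make S and p erratic.
* three or four sparse quadrants, or two sparse quadrants sharing a row
  or column: NONE with a diagnostic flag. These only arise for extreme
  marginals on small totals and have no defined interpretation.

Symmetric relations take precedence: sparse (0,1) and (1,0) ⇒
EQUIVALENT, sparse (0,0) and (1,1) ⇒ OPPOSITE; a single sparse quadrant
maps to its asymmetric implication ((0,0) ⇒ low⇒high, (0,1) ⇒ low⇒low,
(1,0) ⇒ high⇒high, (1,1) ⇒ high⇒low).

## Pair score and slope symmetrization

`score = r² + s²` with r the Pearson correlation of the raw log2 values
(all pairwise-complete samples; intermediate calls are *not* excluded
here, since correlation and regression operate on expression, not on
calls). The slope rule "if s > 1 use 1/s" makes the slope component
scale-free; however the reciprocal of the B-on-A slope is not exactly
invariant under swapping the pair (the two directed slopes multiply to
r²). Since the score matrix is consumed as a symmetric object (row
sorting plus rank weighting), we use s = min(slope_B|A, slope_A|B) =
r·min(sd_B/sd_A, sd_A/sd_B), which coincides with the reciprocal rule
whenever the relation is exactly linear and makes the matrix exactly
symmetric. Negative r or s are floored at 0 before squaring, so
anti-correlated pairs score near 0; the score lies in [0, 2] with 2 only
for perfectly correlated, equal-variance pairs. The diagonal self-score
2 is included in every row: it contributes the same rank term to every
row and cannot reorder probes, while keeping the rank sum running over
exactly len(L) entries.

## Selection threshold on gene scores

The gs values of the candidate list are themselves thresholded with the
step fit. One subtlety: the fit operates on *sorted* data, and sorted
draws from even a perfectly homogeneous distribution form a ramp on
which a step fit always "finds" a split. Applied naively this would
always discard part of a clean marker cluster. The fitted split is
therefore applied only when its explained-variance ratio ssr/sst is
significantly larger than expected for sorted iid Gaussian values of
the same length (one-sided parametric bootstrap, 999 simulations, level
0.001, fixed internal seed so results are reproducible); otherwise the
candidate list is a single cluster of high scorers and every candidate
is selected. This generalizes the obvious degenerate rule (exactly
constant gs ⇒ select all) to the statistically indistinguishable case.
The threshold itself is still reported and used for the Z-test either
way.

## Empirical null and the Z-test

The null score distribution is estimated from pairs sampled uniformly
without replacement among distinct non-constant probes (100,000 pairs by
default; constant probes are excluded because their correlation is
undefined). The gs null moments use the rank-weight identities
E[gs] = E[score]·(len(L)−1)/4 and sd(gs) = sd(score)·(len(L)−1)/4. Both
treat the k-th smallest score in a row as an exchangeable draw from the
score distribution; for a rank-weighted sum of *order statistics* this
is an approximation that is biased low whenever the score distribution
has spread, and noticeably so under heavy right-skew (the typical
compendium: a near-zero mass of unrelated pairs plus a thin tail of
genuinely co-expressed pairs near 2). The identities are implemented as
printed and labeled an approximation; the simulation helper
`simulate_mean_gs` quantifies the gap by building iid-score rows from
the empirical distribution. Because a handful of skewed rows badly
underestimates its own dispersion, the helper estimates the Monte-Carlo
standard error of the small-row mean from 4000 auxiliary rows. The
Z-test for the selected threshold is one-sided (high scores are the
signal).

## Synthetic compendium

The generator emulates the geometry that makes universal markers
discoverable in bulk data: a latent per-sample target-cell abundance f
(60% of samples near zero, 40% uniform on (0.05, 1]) reproduces the
dense low-low corner plus diffuse high arm of real marker-vs-marker
scatterplots. Universal probes emit the high state exactly in
target-positive samples; subset probes only when the sample is
target-positive *and* its subset program is active (Bernoulli,
prevalence 0.4), which plants the asymmetric subset-high ⇒
universal-high implication; noise probes are bimodal with a random
per-probe mixing fraction, independent of f. Levels default to low mean
4.0, high mean 9.0, within-state SD 0.7 log2 units, mimicking
RMA-normalized array dynamic range. Defaults are configuration, not
constants; a fixed seed reproduces matrices bit-identically.

Purified populations draw every sample at f ≈ 1 ("target") or f ≈ 0
("other"), with a small contamination fraction (3%) of opposite-state
samples representing sorting impurity. The contamination matters: it
gives each gene's observed range a realistic far tail, so the
middle-of-range threshold used by the co-expression validation falls
between the states rather than inside a single tight cluster. Subset
markers remain bimodal even in pure target data (prevalence < 1), which
is precisely why the variance F-test flags them as less stable than
universal markers.

What the generator does *not* emulate: platform/batch effects,
probe-level affinity differences, mixtures of more than one structured
cell type, count noise of single-cell data, or dropout. Passing the
planted-recovery tests therefore shows the machinery is correct and
well-calibrated under the stated model, not that discovery is robust to
real-data artifacts.

## Evaluation statistics

* **High-high fraction**: per-gene thresholds at the middle of the
  observed range (the red-line convention of purified-marker
  scatterplots) or from the step fit; "high" is strictly above the
  threshold. Constant genes make the midrange undefined and raise.
* **Variance F-test**: two-sided, statistic = larger/smaller sample
  variance with (n−1, n−1) degrees of freedom; direction is read off
  the reported standard deviations. Zero variance yields a degenerate
  sentinel rather than a p-value.
* **Correlation ranking**: candidates ordered by Pearson r with the
  reference, ties broken by gene id, undefined correlations (constant
  genes) placed last.

## Problem sizes and defaults

The benchmark compendium is 2030 probes (20 universal, 10 subset, 2000
noise) × 1000 samples — large enough that the implication statistics
operate in their intended regime (hundreds of informative samples per
pair, S ≈ 15 for a perfect equivalence) while a full pipeline run takes
a few seconds. Note that very strict sparsity cutoffs interact with
sample size: S cannot exceed √n̂, so S > 50 is only attainable in
compendia with tens of thousands of samples; at n = 1000 it empties the
equivalence network, which is the expected monotone behavior, not a
failure. The empirical null uses 100,000 pairs; the independence
false-positive benchmark uses 1000 multinomial tables of 200 samples
with marginals uniform in (0.25, 0.75).

## Known limitations

* Boolean relations are estimated per pair with plug-in thresholds; no
  multiple-testing control is applied across the genome-wide scan (the
  S > 3 ∧ p < 0.1 rule is itself strongly conservative, as the
  independence benchmark shows).
* The gs null treats scores as iid; see the order-statistics caveat
  above. The Z-test p-values are accordingly indicative rather than
  exact.
* Single-cell inputs are accepted as matrices (optionally via a
  log2(x+1) flag), but no single-cell-specific normalization or
  dropout model is provided.
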