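import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from becc import (
    HIGH,
    INTERMEDIATE,
    LOW,
    MISSING,
    ExpressionMatrix,
    booleanize,
    fit_step,
    threshold_probe,
)


def step_fit_oracle(values):
    """Exhaustive O(n^2) reference: recompute sse from scratch at every k."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    best = None
    for k in range(1, n):
        mu_low = x[:k].mean()
        mu_high = x[k:].mean()
        sse = ((x[:k] - mu_low) ** 2).sum() + ((x[k:] - mu_high) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, mu_low, mu_high)
    sse, k, mu_low, mu_high = best
    return k, sse, 0.5 * (mu_low + mu_high)


class TestFitStep:
    def test_exact_two_level_data(self):
        fit = fit_step([1, 1, 1, 5, 5, 5])
        assert fit.k == 3
        assert fit.mu_low == 1.0
        assert fit.mu_high == 5.0
        assert fit.threshold == 3.0
        assert fit.sse == 0.0

    def test_matches_bruteforce_on_noisy_step(self):
        values = [0.8, 1.0, 1.2, 4.9, 5.0, 5.1]
        fit = fit_step(values)
        k, sse, thr = step_fit_oracle(values)
        assert fit.k == k
        assert fit.threshold == pytest.approx(thr)
        assert fit.sse == pytest.approx(sse)

    def test_constant_vector_is_degenerate(self):
        fit = fit_step([2, 2, 2, 2])
        assert fit.degenerate
        assert fit.threshold == 2.0
        assert fit.sse == 0.0
        assert fit.fstat == np.inf

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            fit_step([1.0])

    def test_unsorted_input_is_sorted_internally(self, rng):
        values = rng.normal(size=40)
        assert fit_step(values).threshold == pytest.approx(
            fit_step(np.sort(values), already_sorted=True).threshold
        )

    def test_oracle_equivalence_random_vectors(self, rng):
        # mix of unimodal and genuinely stepped vectors
        for _ in range(200):
            n = int(rng.integers(2, 120))
            x = rng.normal(size=n)
            if rng.random() < 0.5:
                x[rng.random(n) < 0.5] += 5.0
            fit = fit_step(x)
            k, sse, thr = step_fit_oracle(x)
            assert fit.k == k
            assert fit.sse == pytest.approx(sse, abs=1e-9)
            assert fit.threshold == pytest.approx(thr)

    def test_variance_decomposition(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(3, 80)))
            fit = fit_step(x)
            sst = ((x - x.mean()) ** 2).sum()
            assert fit.ssr + fit.sse == pytest.approx(sst, rel=1e-9)

    def test_fstat_affine_invariant(self, rng):
        x = rng.normal(size=60)
        f1 = fit_step(x).fstat
        f2 = fit_step(3.7 * x + 11.0).fstat
        assert f1 == pytest.approx(f2, rel=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50,
                      allow_nan=False, allow_infinity=False),
            min_size=2, max_size=40,
        )
    )
    def test_fit_matches_oracle_on_arbitrary_lists(self, values):
        fit = fit_step(values)
        k, sse, thr = step_fit_oracle(values)
        assert fit.k == k
        assert fit.sse == pytest.approx(sse, abs=1e-7)
        assert fit.threshold == pytest.approx(thr, abs=1e-9)
        sst = float(((np.sort(values) - np.mean(values)) ** 2).sum())
        assert fit.ssr + fit.sse == pytest.approx(sst, abs=1e-7)

    def test_threshold_affine_equivariant(self, rng):
        x = rng.normal(size=200)
        a, b = 2.5, -4.0
        assert threshold_probe(a * x + b) == pytest.approx(
            a * threshold_probe(x) + b
        )


def _matrix(rows, probe_ids=None, mask=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    probe_ids = probe_ids or [f"P{i}" for i in range(rows.shape[0])]
    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=[f"S{j}" for j in range(rows.shape[1])],
        values=rows,
        mask=mask,
    )


class TestBooleanize:
    def test_two_level_probe(self):
        calls = booleanize(_matrix([[1, 1, 5, 5]]), margin=0.5)
        assert list(calls.codes[0]) == [LOW, LOW, HIGH, HIGH]
        assert calls.thresholds[0] == pytest.approx(3.0)

    def test_boundary_value_is_intermediate(self):
        # threshold 3, margin 2: the values sit exactly at threshold +/- margin
        # and the boundary closes into the intermediate band
        calls = booleanize(_matrix([[1, 1, 5, 5]]), margin=2.0)
        assert (calls.codes[0] == INTERMEDIATE).all()

    def test_zero_margin_leaves_no_intermediate_calls(self):
        # with margin 0 only a value exactly at the threshold could stay
        # intermediate; generic bimodal data has none
        calls = booleanize(_matrix([[1, 1, 2, 5, 5, 6]]), margin=0.0)
        assert (calls.codes[0] != INTERMEDIATE).all()
        assert list(calls.codes[0]) == [LOW, LOW, LOW, HIGH, HIGH, HIGH]

    def test_missing_stays_missing(self):
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, 1] = True
        calls = booleanize(_matrix([[1, 1, 5, 5]], mask=mask), margin=0.5)
        assert calls.codes[0][1] == MISSING

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            booleanize(_matrix([[1, 2, 3, 4]]), margin=-0.1)

    def test_monotone_in_single_value(self, rng):
        """Raising one value never moves its call from HIGH toward LOW."""
        order = {LOW: 0, INTERMEDIATE: 1, HIGH: 2}
        for _ in range(25):
            x = rng.normal(size=30)
            x[rng.random(30) < 0.5] += 4.0
            i = int(rng.integers(30))
            before = booleanize(_matrix([x])).codes[0][i]
            x2 = x.copy()
            x2[i] += float(rng.uniform(0.1, 3.0))
            after = booleanize(_matrix([x2])).codes[0][i]
            assert order[after] >= order[before]
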