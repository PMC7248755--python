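"""Similarity metrics: FFT-magnitude MSE, exact and approximate DTW,
envelope cross-correlation."""

import numpy as np
import pytest

from emgaug.errors import DegenerateInputError, InvalidArgumentError
from emgaug.metrics import (MetricReport, dtw_exact, dtw_fast,
                            envelope_cross_correlation, evaluate_batch,
                            fft_mse)


def naive_fft_mse(a, b):
    n = len(a)
    k = np.arange(n // 2 + 1)
    j = np.arange(n)
    M = np.exp(-2j * np.pi * np.outer(k, j) / n)
    ma, mb = np.abs(M @ a), np.abs(M @ b)
    acc = 0.0
    for x, y in zip(ma, mb):
        acc += (x - y) ** 2
    return acc / len(ma)


def memoized_dtw(a, b):
    """Independent recursive-memoized DTW oracle."""
    import functools
    import sys
    sys.setrecursionlimit(100000)

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return abs(a[0] - b[0])
        if i == 0:
            return rec(0, j - 1) + abs(a[0] - b[j])
        if j == 0:
            return rec(i - 1, 0) + abs(a[i] - b[0])
        return abs(a[i] - b[j]) + min(rec(i - 1, j), rec(i, j - 1),
                                      rec(i - 1, j - 1))

    return rec(len(a) - 1, len(b) - 1)


class TestFftMse:
    def test_identical_signals_zero(self, rng):
        x = rng.standard_normal(64)
        assert fft_mse(x, x) == 0.0

    def test_circular_shift_invariance(self, rng):
        x = rng.standard_normal(128)
        assert fft_mse(x, np.roll(x, 31)) < 1e-9

    def test_matches_naive_oracle(self, rng):
        a, b = rng.standard_normal(64), rng.standard_normal(64)
        assert fft_mse(a, b) == pytest.approx(naive_fft_mse(a, b), abs=1e-9)

    def test_length_mismatch_names_both(self):
        with pytest.raises(InvalidArgumentError, match="10 and 12"):
            fft_mse(np.zeros(10), np.zeros(12))

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        assert fft_mse(a, b) == pytest.approx(fft_mse(b, a), abs=1e-9)

    def test_amplitude_scaling_increases(self, rng):
        a = rng.standard_normal(64)
        b = rng.standard_normal(64)
        assert fft_mse(a, 2 * a) > 0
        assert fft_mse(2 * a, b) != fft_mse(a, b)


class TestDtwExact:
    def test_identical_zero(self, rng):
        x = rng.standard_normal(30)
        assert dtw_exact(x, x) == 0.0

    def test_warping_absorbs_repeats(self):
        assert dtw_exact([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]) == 0.0

    def test_matches_memoized_oracle(self, rng):
        for _ in range(3):
            a = rng.standard_normal(50)
            b = rng.standard_normal(50)
            assert dtw_exact(a, b) == pytest.approx(memoized_dtw(a, b),
                                                    abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(35)
        assert dtw_exact(a, b) == pytest.approx(dtw_exact(b, a), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dtw_exact([], [1.0])

    def test_amplitude_scaling_increases(self, rng):
        a = np.abs(rng.standard_normal(30)) + 0.5
        assert dtw_exact(a, 2 * a) > dtw_exact(a, a)


class TestDtwFast:
    def test_identical_zero(self, rng):
        x = rng.standard_normal(200)
        assert dtw_fast(x, x) == 0.0

    def test_short_sequences_equal_exact(self, rng):
        # below the coarsening base case the recursion bottoms out
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        assert dtw_fast(a, b, radius=1) == pytest.approx(dtw_exact(a, b),
                                                         abs=1e-12)

    def test_never_underestimates(self, rng):
        for _ in range(20):
            a = rng.standard_normal(80)
            b = rng.standard_normal(80)
            assert dtw_fast(a, b, radius=1) >= dtw_exact(a, b) - 1e-9

    def test_mean_relative_error_small(self, rng):
        errs = []
        for _ in range(20):
            a = rng.standard_normal(150)
            b = rng.standard_normal(150)
            exact = dtw_exact(a, b)
            errs.append((dtw_fast(a, b, radius=1) - exact) / exact)
        assert np.mean(errs) <= 0.05

    def test_invalid_radius(self):
        with pytest.raises(InvalidArgumentError):
            dtw_fast([1.0], [1.0], radius=0)


class TestEnvelopeCrossCorrelation:
    def test_identical_is_one(self, rng):
        x = rng.standard_normal(1000)
        assert envelope_cross_correlation(x, x) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_lag_search_recovers_shift(self):
        # 5 Hz burst envelope, one copy delayed by 50 samples
        gen = np.random.default_rng(11)
        t = np.arange(2000) / 2000.0
        gate = (np.sin(2 * np.pi * 5 * t) > 0).astype(float)
        a = gate * gen.standard_normal(2000)
        b = np.concatenate([np.zeros(50), a[:-50]])
        assert envelope_cross_correlation(a, b) >= 0.95

    def test_positive_scale_invariance(self, rng):
        a = rng.standard_normal(800)
        b = rng.standard_normal(800)
        r1 = envelope_cross_correlation(a, b)
        r2 = envelope_cross_correlation(3.7 * a, b)
        r3 = envelope_cross_correlation(a, 0.2 * b)
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert r1 == pytest.approx(r3, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.standard_normal(600), rng.standard_normal(600)
        assert envelope_cross_correlation(a, b) == pytest.approx(
            envelope_cross_correlation(b, a), abs=1e-9)

    def test_anticorrelated_envelopes_far_from_one(self):
        # envelope(b) is the negated-and-recentred envelope(a) (window=1
        # makes the envelope the rectified signal itself); zero lag gives
        # perfect anticorrelation, so the peak stays well below +1
        t = np.linspace(-3, 3, 500)
        a = np.exp(-t ** 2)                  # smooth non-negative bump
        b = (a.max() + 0.1) - a              # non-negative, inverted shape
        r = envelope_cross_correlation(a, b, window=1)
        assert r < 0.5

    def test_zero_variance_envelope_rejected(self):
        with pytest.raises(DegenerateInputError):
            envelope_cross_correlation(np.ones(300), np.ones(300))

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            envelope_cross_correlation(np.ones(10), np.ones(12))


class TestMetricReport:
    def test_bounds_enforced(self):
        with pytest.raises(InvalidArgumentError):
            MetricReport(dtw=-1.0, fft_mse=0.0, env_xcorr=0.0)
        with pytest.raises(InvalidArgumentError):
            MetricReport(dtw=0.0, fft_mse=0.0, env_xcorr=1.5)

    def test_evaluate_batch_identical_batches(self, rng):
        sigs = [rng.standard_normal(400) for _ in range(3)]
        rep = evaluate_batch(sigs, sigs)
        assert rep.dtw == pytest.approx(0.0, abs=1e-12)
        assert rep.fft_mse == pytest.approx(0.0, abs=1e-12)
        assert rep.env_xcorr == pytest.approx(1.0, abs=1e-9)
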