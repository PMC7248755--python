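"""Signal conditioning applied to every EMG record before training or scoring.

Three steps, mirroring standard surface-EMG practice for tremor analysis:

1. a short moving average (default 10 points at 2 kHz, i.e. 5 ms) to
   suppress high-frequency noise while keeping tremor bursts intact;
2. an affine min-max rescale of the whole record to [-1, +1] followed by
   subtraction of the rescaled signal's mean, so that records from
   different sessions and gains share a common scale (and match the tanh
   output range of the generator);
3. random extraction of fixed-length contiguous windows for batching.

The moving average uses a *trailing* window with partial-window warm-up:
output length always equals input length, which keeps generated and
reference signals comparable sample-for-sample.  Rescale statistics are
computed per record (not per window), and per channel for multi-channel
files.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .signal import EmgSignal

__all__ = ["moving_average", "moving_average_array", "condition", "sample_window"]


def moving_average_array(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average of a 1-D array, length-preserving.

    Point ``i`` of the output is the mean of ``x[max(0, i-window+1) : i+1]``:
    the first ``window - 1`` points average only the samples available so
    far (warm-up), every later point averages exactly ``window`` samples.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if window < 1:
        raise InvalidArgumentError(f"window must be >= 1, got {window}")
    if window > n:
        raise InvalidArgumentError(
            f"window ({window}) exceeds signal length ({n})")
    if window == 1:
        return x.copy()
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    start = np.maximum(idx - window + 1, 0)
    counts = idx - start + 1
    return (csum[idx + 1] - csum[start]) / counts


def moving_average(signal: EmgSignal, window: int) -> EmgSignal:
    """Apply a trailing ``window``-point moving average (length-preserving)."""
    return signal.with_samples(moving_average_array(signal.samples, window))


def condition(signal: EmgSignal) -> EmgSignal:
    """Rescale to [-1, +1] (min-max, per record) then subtract the mean.

    The post-subtraction mean is zero to within 1e-9; the range may
    slightly exceed [-1, 1] after the mean shift, which is accepted.

    Raises
    ------
    DegenerateInputError
        If the signal is constant (min == max: the rescale is undefined).
    """
    x = signal.samples
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateInputError(
            "condition() requires a non-constant signal (min < max); "
            f"got constant value {lo}")
    scaled = -1.0 + 2.0 * (x - lo) / (hi - lo)
    scaled -= scaled.mean()
    return signal.with_samples(scaled)


def sample_window(signal: EmgSignal, length: int,
                  rng: int | np.random.Generator) -> EmgSignal:
    """Extract a random contiguous window of exactly ``length`` samples.

    The start index is uniform over all valid starts; ``rng`` may be a
    seed (same seed, same slice) or an existing Generator.
    """
    n = len(signal)
    if length < 1 or length > n:
        raise InvalidArgumentError(
            f"window length ({length}) must be in [1, {n}]")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    start = int(gen.integers(0, n - length + 1))
    return signal.with_samples(signal.samples[start:start + length])
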