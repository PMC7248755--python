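"""Synthetic surface-EMG generators used as offline stand-ins for real data.

Two signal families are emulated:

* **Rest-tremor EMG** (`synth_tremor`) — quasi-periodic bursts at the
  parkinsonian tremor frequency (default 5 Hz) riding on an EMG-like
  broadband carrier.  The carrier is Gaussian white noise band-passed to
  20-450 Hz (the usual surface-EMG band); each tremor cycle is gated by
  a raised-cosine bump covering ``burst_duty`` of the cycle, with
  per-burst amplitude jitter.  The envelope spectrum therefore peaks at
  the tremor frequency and its harmonics.

* **Healthy functional-movement EMG** (`synth_movement`) — repetitions
  of a 5 s activation (smooth onset/offset ramps) followed by 3 s of
  near-silence, emulating wrist flexion/extension protocol recordings.

Both outputs are conditioned (min-max rescale to [-1, 1], mean
subtraction) before being returned, and are fully determined by their
seed.  These generators emulate burst timing, spectral band, and
amplitude statistics — not motor-unit physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import InvalidArgumentError
from .preprocess import condition
from .signal import EmgSignal

__all__ = ["TremorParams", "MovementParams", "synth_tremor", "synth_movement"]


@dataclass(frozen=True)
class TremorParams:
    """Parameters of the rest-tremor generator.

    tremor_freq : burst repetition rate in Hz (parkinsonian rest tremor
        sits near 4-6 Hz; default 5).
    burst_duty : fraction of each tremor cycle that is active (0, 1].
    carrier_band : (low, high) Hz of the broadband carrier.
    amp_jitter : relative std of per-burst amplitude variation.
    baseline : background noise level relative to carrier amplitude.
    """

    tremor_freq: float = 5.0
    rate: float = 2000.0
    duration: float = 1.0
    burst_duty: float = 0.5
    carrier_band: tuple[float, float] = (20.0, 450.0)
    amp_jitter: float = 0.1
    baseline: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tremor_freq < self.rate / 2:
            raise InvalidArgumentError(
                f"tremor_freq must be in (0, rate/2), got {self.tremor_freq}")
        if not 0 < self.burst_duty <= 1:
            raise InvalidArgumentError(
                f"burst_duty must be in (0, 1], got {self.burst_duty}")
        if self.duration <= 0 or self.rate <= 0:
            raise InvalidArgumentError("duration and rate must be positive")
        if self.amp_jitter < 0 or self.baseline < 0:
            raise InvalidArgumentError("amp_jitter and baseline must be >= 0")


@dataclass(frozen=True)
class MovementParams:
    """Parameters of the functional-movement generator (5 s on / 3 s off)."""

    active_s: float = 5.0
    rest_s: float = 3.0
    n_repetitions: int = 2
    rate: float = 2000.0
    ramp_s: float = 0.5
    carrier_band: tuple[float, float] = (20.0, 450.0)
    baseline: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.active_s <= 0 or self.rest_s <= 0:
            raise InvalidArgumentError("active_s and rest_s must be positive")
        if self.n_repetitions < 1:
            raise InvalidArgumentError("n_repetitions must be >= 1")
        if self.rate <= 0:
            raise InvalidArgumentError("rate must be positive")


def _bandpassed_noise(n: int, rate: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian white noise band-passed with a zero-phase Butterworth."""
    noise = rng.standard_normal(n)
    low, high = band
    high = min(high, 0.45 * rate)  # keep below Nyquist for low test rates
    if low >= high:
        return noise
    sos = scipy.signal.butter(4, [low, high], btype="bandpass",
                              fs=rate, output="sos")
    return scipy.signal.sosfiltfilt(sos, noise)


def synth_tremor(p: TremorParams) -> EmgSignal:
    """Generate one conditioned rest-tremor EMG record."""
    n = int(round(p.duration * p.rate))
    rng = np.random.default_rng(p.seed)
    carrier = _bandpassed_noise(n, p.rate, p.carrier_band, rng)
    carrier /= max(np.abs(carrier).max(), 1e-12)

    t = np.arange(n) / p.rate
    cycle_pos = (t * p.tremor_freq) % 1.0          # position within cycle
    cycle_idx = np.floor(t * p.tremor_freq).astype(int)
    # raised-cosine bump over the active fraction of each cycle
    gate = np.where(cycle_pos < p.burst_duty,
                    0.5 * (1.0 - np.cos(2.0 * np.pi * cycle_pos
                                        / p.burst_duty)),
                    0.0)
    n_cycles = cycle_idx.max() + 1
    burst_amp = np.clip(1.0 + p.amp_jitter * rng.standard_normal(n_cycles),
                        0.1, None)
    gate = gate * burst_amp[cycle_idx]

    background = p.baseline * rng.standard_normal(n)
    raw = carrier * gate + background
    sig = EmgSignal(raw, rate=p.rate,
                    label=f"synthetic-tremor-{p.tremor_freq:g}Hz-seed{p.seed}")
    return condition(sig)


def synth_movement(p: MovementParams) -> EmgSignal:
    """Generate one conditioned functional-movement EMG record.

    Length is exactly ``n_repetitions * (active_s + rest_s) * rate``
    samples.
    """
    n_active = int(round(p.active_s * p.rate))
    n_rest = int(round(p.rest_s * p.rate))
    n_total = p.n_repetitions * (n_active + n_rest)
    rng = np.random.default_rng(p.seed)
    carrier = _bandpassed_noise(n_total, p.rate, p.carrier_band, rng)
    carrier /= max(np.abs(carrier).max(), 1e-12)

    n_ramp = max(1, min(int(round(p.ramp_s * p.rate)), n_active // 2))
    gate_cycle = np.zeros(n_active + n_rest)
    gate_cycle[:n_active] = 1.0
    ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n_ramp)))
    gate_cycle[:n_ramp] = ramp
    gate_cycle[n_active - n_ramp:n_active] = ramp[::-1]
    gate = np.tile(gate_cycle, p.n_repetitions)

    background = p.baseline * rng.standard_normal(n_total)
    raw = carrier * gate + background
    sig = EmgSignal(raw, rate=p.rate,
                    label=f"synthetic-movement-seed{p.seed}")
    return condition(sig)
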