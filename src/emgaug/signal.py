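"""The :class:`EmgSignal` container — the currency passed between modules.

A surface-EMG record is a one-dimensional sequence of amplitude samples
taken at a fixed sampling rate (2 kHz for the wrist recordings this
package emulates).  Amplitudes are dimensionless after conditioning
(min-max rescale to [-1, 1] plus mean subtraction) and raw volts before.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

DEFAULT_RATE_HZ = 2000.0


@dataclass(frozen=True)
class EmgSignal:
    """A single-channel EMG time series.

    Parameters
    ----------
    samples
        Real-valued amplitude sequence; must be non-empty and finite.
    rate
        Sampling frequency in Hz (> 0).  Default 2000.
    label
        Free-text provenance tag (patient id, channel name, "synthetic", ...).
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE_HZ
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            arr = arr.reshape(-1)
        if arr.size == 0:
            raise InvalidArgumentError("EmgSignal.samples must be non-empty")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("EmgSignal.samples must be finite (no NaN/Inf)")
        if not self.rate > 0:
            raise InvalidArgumentError(f"EmgSignal.rate must be > 0, got {self.rate}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.rate

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "EmgSignal":
        """Return a copy carrying new samples (same rate, optionally new label)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       label=self.label if label is None else label)
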