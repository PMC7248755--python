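"""Feature transforms shared by the discriminator pipelines and the
style-transfer losses.

Four views of a conditioned EMG window are used throughout the package:

* **raw** — the signal itself;
* **fft_mag** — magnitude of the real-input FFT (phase discarded; tremor
  shows up as a peak near 5 Hz and its harmonics);
* **envelope** — rectified signal smoothed with a 100-point moving
  average, the standard burst-amplitude tracker for surface EMG;
* **wavelet** — 2-level discrete wavelet decomposition (Daubechies db7),
  coefficients concatenated coarsest-first.

`gram_matrix` computes the position-invariant "style" representation:
inner products between feature maps.

The DWT is also exposed as a sparse linear operator (`dwt_operator`) so
gradients can be propagated through it during style optimization; the
operator is built once per (length, wavelet, level) and cached.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
import scipy.sparse as sp

from .errors import InvalidArgumentError
from .preprocess import moving_average_array
from .signal import EmgSignal

__all__ = [
    "fft_magnitude", "envelope", "dwt_features", "dwt_operator",
    "gram_matrix", "FeatureStack", "feature_stack",
    "DWT_WAVELET", "DWT_LEVEL", "DWT_MODE", "ENVELOPE_WINDOW",
]

DWT_WAVELET = "db7"
DWT_LEVEL = 2
# Symmetric (half-sample) boundary extension: fixed so coefficient
# lengths are reproducible across runs and platforms.
DWT_MODE = "symmetric"
ENVELOPE_WINDOW = 100


def _as_array(signal: EmgSignal | np.ndarray) -> np.ndarray:
    if isinstance(signal, EmgSignal):
        return signal.samples
    return np.asarray(signal, dtype=np.float64).reshape(-1)


def fft_magnitude(signal: EmgSignal | np.ndarray) -> np.ndarray:
    """Magnitude spectrum of the real-input FFT.

    Returns a non-negative vector of length ``n//2 + 1`` with the DC bin
    first.  A pure sinusoid of amplitude ``a`` at bin ``k`` produces a
    single peak of magnitude ``a*n/2`` at index ``k``.
    """
    x = _as_array(signal)
    if x.size < 2:
        raise InvalidArgumentError(
            f"fft_magnitude requires length >= 2, got {x.size}")
    return np.abs(np.fft.rfft(x))


def envelope(signal: EmgSignal | np.ndarray,
             window: int = ENVELOPE_WINDOW) -> np.ndarray:
    """EMG envelope: absolute value followed by a trailing moving average."""
    x = _as_array(signal)
    return moving_average_array(np.abs(x), window)


def _min_dwt_length(wavelet: str, level: int) -> int:
    # each decomposition level needs at least filter_len - 1 samples
    w = pywt.Wavelet(wavelet)
    return max(2 ** level, (w.dec_len - 1) * 2 ** (level - 1) + 1)


def dwt_features(signal: EmgSignal | np.ndarray,
                 wavelet_name: str = DWT_WAVELET,
                 level: int = DWT_LEVEL) -> np.ndarray:
    """Concatenated multi-level DWT coefficients, coarsest-first.

    For the default 2-level db7 transform the output is
    ``[approx_2, detail_2, detail_1]``.
    """
    x = _as_array(signal)
    min_len = _min_dwt_length(wavelet_name, level)
    if x.size < min_len:
        raise InvalidArgumentError(
            f"signal length {x.size} too short for a {level}-level "
            f"{wavelet_name} DWT (needs >= {min_len} samples)")
    coeffs = pywt.wavedec(x, wavelet_name, mode=DWT_MODE, level=level)
    return np.concatenate(coeffs)


def dwt_coeff_slices(length: int, wavelet_name: str = DWT_WAVELET,
                     level: int = DWT_LEVEL) -> list[slice]:
    """Slices of the concatenated coefficient vector for each band."""
    lens = [len(c) for c in pywt.wavedec(np.zeros(length), wavelet_name,
                                         mode=DWT_MODE, level=level)]
    edges = np.concatenate(([0], np.cumsum(lens)))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@lru_cache(maxsize=8)
def dwt_operator(length: int, wavelet_name: str = DWT_WAVELET,
                 level: int = DWT_LEVEL) -> sp.csr_matrix:
    """The DWT as a sparse matrix ``W`` with ``dwt_features(x) == W @ x``.

    Built column-by-column from unit impulses (each impulse touches only
    O(filter_len * level) coefficients, so W is sparse).  The transpose
    is the adjoint used for gradient propagation.
    """
    cols = []
    e = np.zeros(length)
    for j in range(length):
        e[j] = 1.0
        cols.append(sp.csc_matrix(dwt_features(e, wavelet_name, level)).T)
        e[j] = 0.0
    return sp.hstack(cols).tocsr()


def gram_matrix(feature_maps: np.ndarray) -> np.ndarray:
    """Gram matrix of a set of feature maps.

    ``feature_maps`` is an ``N_l x M_l`` matrix (one row per feature map,
    one column per position); the result is the ``N_l x N_l`` matrix of
    inner products ``G[i, j] = sum_k F[i, k] * F[j, k]`` — symmetric,
    positive semi-definite, and invariant to position permutations.
    """
    F = np.asarray(feature_maps, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 1 or F.shape[1] < 1:
        raise InvalidArgumentError(
            f"gram_matrix expects a non-empty 2-D matrix, got shape {F.shape}")
    return F @ F.T


@dataclass(frozen=True)
class FeatureStack:
    """The four per-pipeline feature vectors for one signal."""

    raw: np.ndarray
    fft_mag: np.ndarray
    envelope: np.ndarray
    wavelet: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"raw": self.raw, "fft": self.fft_mag,
                "envelope": self.envelope, "wavelet": self.wavelet}


def feature_stack(signal: EmgSignal,
                  envelope_window: int = ENVELOPE_WINDOW) -> FeatureStack:
    """Compute all four feature views of a signal."""
    return FeatureStack(
        raw=signal.samples.copy(),
        fft_mag=fft_magnitude(signal),
        envelope=envelope(signal, envelope_window),
        wavelet=dwt_features(signal),
    )
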