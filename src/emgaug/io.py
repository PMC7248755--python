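"""Delimited-file I/O for EMG records.

The on-disk dialect is deliberately minimal: a header row of channel
names, one numeric column per channel, one row per sample tick.  The
sampling rate is not stored in the file; it is supplied by the caller
(CLI flag ``--rate``, default 2000 Hz).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CsvFormatError
from .signal import EmgSignal

__all__ = ["read_emg_csv", "write_emg_csv"]


def read_emg_csv(path: str | Path, rate: float = 2000.0) -> list[EmgSignal]:
    """Read a delimited EMG file into one :class:`EmgSignal` per column.

    Channel order is preserved; the channel name (header) becomes the
    signal label.  Raises :class:`CsvFormatError` for a missing file,
    an empty/header-only file, ragged rows, or non-numeric cells (the
    error names the offending row and column).
    """
    path = Path(path)
    if not path.exists():
        raise CsvFormatError(f"EMG file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CsvFormatError(f"EMG file is empty: {path}") from exc
    except pd.errors.ParserError as exc:
        raise CsvFormatError(f"ragged or malformed rows in {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise CsvFormatError(f"EMG file has a header but no data rows: {path}")
    signals = []
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size and not np.all(np.isfinite(
                pd.to_numeric(df[col], errors="coerce"))):
            row = int(bad[0])
            raise CsvFormatError(
                f"non-numeric or missing value at row {row + 2} "
                f"(1-based, incl. header), column '{col}' in {path}: "
                f"{df[col].iloc[row]!r}")
        signals.append(EmgSignal(values, rate=rate, label=str(col)))
    return signals


def write_emg_csv(path: str | Path, signals: Sequence[EmgSignal] | EmgSignal) -> None:
    """Write one or more equal-length signals as CSV columns."""
    if isinstance(signals, EmgSignal):
        signals = [signals]
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise CsvFormatError(
            f"all channels must have equal length, got lengths {sorted(lengths)}")
    data = {}
    for i, s in enumerate(signals):
        name = s.label or f"ch{i}"
        base, k = name, 1
        while name in data:            # de-duplicate repeated labels
            name = f"{base}_{k}"
            k += 1
        data[name] = s.samples
    pd.DataFrame(data).to_csv(path, index=False)
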