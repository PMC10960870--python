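"""Interval-CSV input/output and the two published interval datasets.

The interval-CSV schema is two numeric columns ``lower,upper``, one row
per unit; a single-column file is read as degenerate intervals.  Rows
printed with the endpoints reversed are auto-swapped with a logged
warning (the alloy melting-point data below is printed high-endpoint
first, so all 18 rows normalize on read).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from .sampling import IntervalSample

__all__ = ["read_interval_csv", "write_interval_csv", "fixtures"]

log = logging.getLogger("neutrobs")

# Melting-point intervals (temperature units) of 18 metal alloys; the
# source prints each pair high endpoint first.
_ALLOY = [
    (563.3, 545.5), (529.4, 511.6), (523.1, 503.5), (470.1, 449.2),
    (506.7, 489.0), (495.6, 479.1), (495.3, 467.9), (520.9, 495.6),
    (496.9, 472.8), (542.9, 519.1), (505.4, 484.0), (550.7, 525.9),
    (517.7, 500.9), (499.2, 483.0), (500.6, 480.0), (516.8, 499.6),
    (535.0, 515.1), (489.3, 464.4),
]

# Lifetimes (in units of 100 hours) of 23 batteries, as intervals.
_BATTERY = [
    (2.9, 3.99), (5.24, 7.2), (6.56, 9.02), (7.14, 9.82), (11.6, 15.96),
    (12.14, 16.69), (12.65, 17.4), (13.24, 18.21), (13.67, 18.79),
    (13.88, 19.09), (15.64, 21.51), (17.05, 23.45), (17.4, 23.93),
    (17.8, 24.48), (19.01, 26.14), (19.34, 26.59), (23.13, 31.81),
    (23.34, 32.09), (26.07, 35.84), (30.29, 41.65), (43.97, 60.46),
    (48.09, 66.13), (73.48, 98.04),
]


def _normalize(arr: np.ndarray, origin: str) -> IntervalSample:
    lower, upper = arr[:, 0].copy(), arr[:, 1].copy()
    swapped = lower > upper
    n_swapped = int(np.sum(swapped))
    if n_swapped:
        lower[swapped], upper[swapped] = upper[swapped], lower[swapped].copy()
        log.warning("%s: swapped %d row(s) printed with lower > upper", origin, n_swapped)
    return IntervalSample(lower, upper)


def read_interval_csv(path) -> IntervalSample:
    """Read an interval sample; validates positivity row by row."""
    path = Path(path)
    df = pd.read_csv(path)
    first = str(df.columns[0])
    try:
        float(first)
    except ValueError:
        pass
    else:  # headerless file: re-read without treating row 1 as a header
        df = pd.read_csv(path, header=None)
    if df.shape[1] == 1:
        df = pd.concat([df.iloc[:, 0], df.iloc[:, 0]], axis=1)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    values = np.empty((len(df), 2))
    for idx, row in enumerate(df.itertuples(index=False)):
        for j, cell in enumerate(row):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValueError(f"{path}, row {idx + 1}: non-numeric cell {cell!r}") from None
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{path}, row {idx + 1}: non-positive value {v}")
            values[idx, j] = v
    return _normalize(values, str(path))


def write_interval_csv(sample: IntervalSample, path) -> None:
    pd.DataFrame({"lower": sample.lower, "upper": sample.upper}).to_csv(path, index=False)


def fixtures() -> Dict[str, IntervalSample]:
    """The two published interval datasets, normalized to lower <= upper."""
    return {
        "alloy": _normalize(np.asarray(_ALLOY, dtype=float), "alloy fixture"),
        "battery": _normalize(np.asarray(_BATTERY, dtype=float), "battery fixture"),
    }
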